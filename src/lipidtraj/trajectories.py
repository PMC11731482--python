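"""Group-based trajectory models (latent-class growth) for longitudinal lipids.

A finite mixture of polynomial mean curves over relative year with a
censored-normal (tobit) observation model and an optional time-varying
on-medication covariate:

    y_it | group g  ~  CensoredNormal( poly(beta_g, t) + alpha_g * med_it, sigma )

fit by EM with multiple random starts.  Subjects may have gappy, unequal visit
schedules; the per-subject likelihood is the product over observed years.
Diagnostics follow the latent-class-growth literature: average posterior
probability of assignment (APP), odds of correct classification (OCC), and the
modal group share.  Model selection sweeps group counts and polynomial orders
and admits a model only if every group has APP >= 0.85, OCC >= 5 and at least
5% of the cohort; among admissible fits the best BIC wins.  Groups are always
relabelled in ascending order of the fitted mean at relative year 0.

Time is internally scaled as t/10 so polynomial bases are well conditioned;
reported coefficients are on that scale (the year-0 mean is the constant term).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = ["TrajectoryModelSpec", "TrajectoryFit", "censored_normal_loglik",
           "fit_trajectory_model", "compute_occ", "sweep_and_select", "SweepResult"]

_TIME_SCALE = 10.0


def censored_normal_loglik(y, mu, sigma, y_min=-np.inf, y_max=np.inf):
    """Log-density of a censored normal (tobit) observation model.

    Interior observations get the normal log-density; observations at or below
    ``y_min`` get the lower tail mass log Phi((y_min - mu)/sigma); at or above
    ``y_max`` the upper tail mass.  ``y`` is expected within [y_min, y_max].
    """
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if y_min >= y_max:
        raise ValueError("y_min must be below y_max")
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    out = norm.logpdf(y, mu, sigma)
    lo = y <= y_min
    hi = y >= y_max
    if np.any(lo):
        out = np.where(lo, norm.logcdf((y_min - mu) / sigma), out)
    if np.any(hi):
        out = np.where(hi, norm.logsf((y_max - mu) / sigma), out)
    return out if out.ndim else float(out)


@dataclass
class TrajectoryModelSpec:
    """Specification of one trajectory mixture model."""
    n_groups: int
    poly_order: object = 2            # int (shared) or sequence per group
    y_min: float | None = None        # None -> data min, padded to be inert
    y_max: float | None = None
    include_med_covariate: bool = True
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def orders(self):
        if np.isscalar(self.poly_order):
            return [int(self.poly_order)] * self.n_groups
        orders = [int(o) for o in self.poly_order]
        if len(orders) != self.n_groups:
            raise ValueError("per-group orders must match n_groups")
        return orders

    def validate(self):
        if not 1 <= self.n_groups <= 5:
            raise ValueError("n_groups must be in 1..5")
        if any(not 0 <= o <= 4 for o in self.orders()):
            raise ValueError("polynomial orders must be in 0..4")
        if self.y_min is not None and self.y_max is not None and self.y_min >= self.y_max:
            raise ValueError("y_min must be below y_max")


@dataclass
class TrajectoryFit:
    spec: TrajectoryModelSpec
    pi: np.ndarray                    # mixing proportions, ascending year-0 mean
    coefs: list                       # per-group polynomial coefficients (t/10 basis)
    med_effects: np.ndarray           # per-group medication shift (0 if excluded)
    sigma: float
    loglik: float
    n_params: int
    n_subjects: int
    aic: float
    bic: float
    posteriors: pd.DataFrame          # subject_id x group columns g1..gG
    assignments: pd.Series            # modal group per subject (1-based)
    app: np.ndarray
    occ: np.ndarray
    shares: np.ndarray
    converged: bool
    degenerate: bool
    coef_covs: list = field(default_factory=list)

    def mean_curve(self, group: int, rel_years=None):
        """Fitted off-medication mean at each relative year for 1-based group."""
        if rel_years is None:
            rel_years = np.arange(-10, 1)
        t = np.asarray(rel_years, float) / _TIME_SCALE
        c = self.coefs[group - 1]
        X = np.vander(t, len(c), increasing=True)
        return X @ c

    def fitted_curves(self, rel_years=None, z=1.96) -> pd.DataFrame:
        """Per-year mean curves with polynomial-fit bands for every group."""
        if rel_years is None:
            rel_years = np.arange(-10, 1)
        t = np.asarray(rel_years, float) / _TIME_SCALE
        rows = []
        for g in range(1, len(self.pi) + 1):
            c = self.coefs[g - 1]
            X = np.vander(t, len(c), increasing=True)
            mean = X @ c
            if self.coef_covs:
                cov = self.coef_covs[g - 1][:len(c), :len(c)]
                se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, cov, X), 0))
            else:
                se = np.zeros_like(mean)
            for yr, m, s in zip(rel_years, mean, se):
                rows.append({"group": g, "rel_year": int(yr), "mean": m,
                             "lo": m - z * s, "hi": m + z * s})
        return pd.DataFrame(rows)


def compute_occ(app, pi):
    """Odds of correct classification per group.

    OCC_g = [APP_g/(1-APP_g)] / [pi_g/(1-pi_g)]; APP_g = 1 maps to +inf.
    """
    app = np.asarray(app, float)
    pi = np.asarray(pi, float)
    if np.any((pi <= 0) | (pi >= 1)):
        if len(pi) == 1 and np.isclose(pi[0], 1.0):
            return np.array([np.inf])
        raise ValueError("mixing proportions must lie in (0, 1)")
    out = np.empty_like(app)
    for i, (a, p) in enumerate(zip(app, pi)):
        if a >= 1.0:
            out[i] = np.inf
        else:
            out[i] = (a / (1 - a)) / (p / (1 - p))
    return out


def _lloyd_1d(x, k, iters=30):
    """Plain 1-D k-means (Lloyd) on subject mean levels, quantile-seeded."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(iters):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[assign == j].mean() if np.any(assign == j) else centers[j]
                        for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def _prepare(data: pd.DataFrame, include_med: bool):
    d = data.sort_values(["subject_id", "rel_year"]).reset_index(drop=True)
    subjects, subj_idx = np.unique(d["subject_id"].to_numpy(), return_inverse=True)
    counts = np.bincount(subj_idx)
    if counts.min() < 3:
        raise ValueError("every subject needs >=3 observed years")
    y = d["value"].to_numpy(dtype=float)
    t = d["rel_year"].to_numpy(dtype=float) / _TIME_SCALE
    med = d["on_med"].to_numpy(dtype=float) if include_med and "on_med" in d else None
    return subjects, subj_idx, y, t, med


def _group_design(X, med, order):
    D = X[:, :order + 1]
    if med is not None:
        D = np.column_stack([D, med])
    return D


def _obs_loglik(y, mu, sigma, y_min, y_max, any_censored):
    if not any_censored:
        return norm.logpdf(y, mu, sigma)
    return censored_normal_loglik(y, mu, sigma, y_min, y_max)


def _wls_mstep(y, designs, w_obs, n_obs):
    coefs, rss = [], 0.0
    for g, D in enumerate(designs):
        w = w_obs[:, g]
        A = D.T @ (D * w[:, None]) + 1e-10 * np.eye(D.shape[1])
        b = D.T @ (w * y)
        c = np.linalg.solve(A, b)
        coefs.append(c)
        rss += float(w @ (y - D @ c) ** 2)
    sigma = np.sqrt(max(rss / n_obs, 1e-12))
    return coefs, sigma


def _pack(coefs, sigma):
    return np.concatenate([np.concatenate(coefs), [np.log(sigma)]])


def _unpack(theta, sizes):
    coefs, k = [], 0
    for s in sizes:
        coefs.append(theta[k:k + s])
        k += s
    return coefs, float(np.exp(theta[-1]))


def _q_value(theta, sizes, y, designs, w_obs, y_min, y_max):
    coefs, sigma = _unpack(theta, sizes)
    q = 0.0
    for g, D in enumerate(designs):
        ll = censored_normal_loglik(y, D @ coefs[g], sigma, y_min, y_max)
        q += float(w_obs[:, g] @ ll)
    return -q


def _em_once(y, designs, subj_idx, n_subj, init_coefs, init_sigma, init_pi,
             y_min, y_max, any_censored, max_iter, tol):
    G = len(designs)
    n_obs = len(y)
    coefs, sigma, pi = list(init_coefs), float(init_sigma), np.asarray(init_pi, float)
    sizes = [D.shape[1] for D in designs]
    ll_prev = -np.inf
    W = np.full((n_subj, G), 1.0 / G)
    converged = False
    for _ in range(max_iter):
        # E-step
        subj_ll = np.empty((n_subj, G))
        for g, D in enumerate(designs):
            oll = _obs_loglik(y, D @ coefs[g], sigma, y_min, y_max, any_censored)
            subj_ll[:, g] = np.bincount(subj_idx, weights=oll, minlength=n_subj)
        logw = subj_ll + np.log(np.maximum(pi, 1e-300))
        lse = logsumexp(logw, axis=1)
        ll = float(lse.sum())
        W = np.exp(logw - lse[:, None])
        if np.isfinite(ll_prev):
            if ll + 1e-8 < ll_prev:
                warnings.warn("EM log-likelihood decreased; stopping at previous iterate")
                break
            if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0):
                ll_prev = ll
                converged = True
                break
        ll_prev = ll
        # M-step
        pi = W.mean(axis=0)
        pi = np.maximum(pi, 1e-12)
        pi /= pi.sum()
        w_obs = W[subj_idx, :]
        new_coefs, new_sigma = _wls_mstep(y, designs, w_obs, n_obs)
        if any_censored:
            # generalized M-step: keep whichever of {old, WLS, refined} has the
            # best complete-data objective, so the mixture loglik cannot drop
            q_old = _q_value(_pack(coefs, sigma), sizes, y, designs, w_obs, y_min, y_max)
            q_wls = _q_value(_pack(new_coefs, new_sigma), sizes, y, designs, w_obs, y_min, y_max)
            start = _pack(new_coefs, new_sigma) if q_wls <= q_old else _pack(coefs, sigma)
            res = optimize.minimize(_q_value, start, method="L-BFGS-B",
                                    args=(sizes, y, designs, w_obs, y_min, y_max),
                                    options={"maxiter": 50})
            cand = [(q_old, (coefs, sigma)), (q_wls, (new_coefs, new_sigma))]
            if np.isfinite(res.fun):
                cand.append((res.fun, _unpack(res.x, sizes)))
            _, (coefs, sigma) = min(cand, key=lambda c: c[0])
            coefs = list(coefs)
        else:
            coefs, sigma = new_coefs, new_sigma
    return coefs, sigma, pi, W, ll_prev, converged


def fit_trajectory_model(data: pd.DataFrame, spec: TrajectoryModelSpec) -> TrajectoryFit:
    """Fit a censored-normal trajectory mixture by multi-start EM.

    ``data`` is a long table with columns subject_id, rel_year, value and
    (optionally) on_med.  Each subject needs >=3 observed years; gaps are fine.
    """
    spec.validate()
    include_med = spec.include_med_covariate and "on_med" in data.columns
    subjects, subj_idx, y, t, med = _prepare(data, include_med)
    n_subj = len(subjects)
    orders = spec.orders()
    G = spec.n_groups
    max_order = max(orders)
    X = np.vander(t, max_order + 1, increasing=True)
    designs = [_group_design(X, med, o) for o in orders]
    # default censoring bounds: data range padded so censoring is inert
    rng_pad = 1e-6 * max(np.ptp(y), 1.0)
    y_min = spec.y_min if spec.y_min is not None else float(y.min() - rng_pad)
    y_max = spec.y_max if spec.y_max is not None else float(y.max() + rng_pad)
    if np.any(y < y_min) or np.any(y > y_max):
        raise ValueError("observations outside censoring bounds")
    any_censored = bool(np.any(y <= y_min) or np.any(y >= y_max))

    ybar = np.bincount(subj_idx, weights=y) / np.bincount(subj_idx)
    rng = np.random.default_rng(spec.seed)
    best = None
    n_starts = 1 if G == 1 else spec.n_starts
    for s in range(n_starts):
        if s == 0:
            centers = _lloyd_1d(ybar, G)     # deterministic k-means start
        else:
            centers = np.sort(rng.choice(ybar, G, replace=False))
        hard = np.argmin(np.abs(ybar[:, None] - centers[None, :]), axis=1)
        W0 = np.zeros((n_subj, G))
        W0[np.arange(n_subj), hard] = 1.0
        W0 = 0.9 * W0 + 0.1 / G
        pi0 = W0.mean(axis=0)
        coefs0, sigma0 = _wls_mstep(y, designs, W0[subj_idx, :], len(y))
        sigma0 = max(sigma0, 1e-3)
        out = _em_once(y, designs, subj_idx, n_subj, coefs0, sigma0, pi0,
                       y_min, y_max, any_censored, spec.max_iter, spec.tol)
        if best is None or out[4] > best[4]:
            best = out
    coefs, sigma, pi, W, loglik, converged = best
    if not converged:
        warnings.warn("trajectory EM did not converge within max_iter; "
                      "fit flagged, diagnostics still reported")

    # deterministic label order: ascending fitted mean at relative year 0
    year0 = np.array([c[0] for c in coefs])
    order = np.argsort(year0, kind="stable")
    coefs = [coefs[g] for g in order]
    pi = pi[order]
    W = W[:, order]
    designs = [designs[g] for g in order]
    orders_sorted = [orders[g] for g in order]

    assign = W.argmax(axis=1)
    shares = np.bincount(assign, minlength=G) / n_subj
    app = np.array([W[assign == g, g].mean() if np.any(assign == g) else np.nan
                    for g in range(G)])
    if G == 1:
        occ = np.array([np.inf])
    else:
        occ = compute_occ(np.where(np.isnan(app), 0.0, app), pi)
        occ = np.where(np.isnan(app), np.nan, occ)
    degenerate = bool(pi.min() < 1e-4 or np.any(shares == 0))
    if degenerate:
        warnings.warn("degenerate fit: a group is (nearly) empty")

    med_eff = np.array([c[-1] if include_med else 0.0 for c in coefs])
    poly_coefs = [c[:-1] if include_med else c for c in coefs]
    w_obs = W[subj_idx, :]
    covs = []
    for g, D in enumerate(designs):
        A = D.T @ (D * w_obs[:, g][:, None]) + 1e-10 * np.eye(D.shape[1])
        covs.append(sigma ** 2 * np.linalg.inv(A))

    n_params = sum(o + 1 for o in orders_sorted) + (G if include_med else 0) + (G - 1) + 1
    posteriors = pd.DataFrame(W, columns=[f"g{g+1}" for g in range(G)])
    posteriors.insert(0, "subject_id", subjects)
    return TrajectoryFit(
        spec=spec, pi=pi, coefs=poly_coefs, med_effects=med_eff, sigma=float(sigma),
        loglik=float(loglik), n_params=n_params, n_subjects=n_subj,
        aic=-2 * loglik + 2 * n_params, bic=-2 * loglik + n_params * np.log(n_subj),
        posteriors=posteriors,
        assignments=pd.Series(assign + 1, index=subjects, name="group"),
        app=app, occ=occ, shares=shares, converged=converged,
        degenerate=degenerate, coef_covs=covs,
    )


@dataclass
class SweepResult:
    report: pd.DataFrame
    chosen: TrajectoryFit | None
    status: str                    # "ok" or "no admissible model"


def _passes(fit: TrajectoryFit, min_app, min_occ, min_share):
    if fit.degenerate or np.any(np.isnan(fit.app)):
        return False
    occ = np.where(np.isinf(fit.occ), np.inf, fit.occ)
    return bool(fit.app.min() >= min_app and occ.min() >= min_occ
                and fit.shares.min() >= min_share)


def sweep_and_select(data: pd.DataFrame, groups=(1, 2, 3, 4, 5), orders=(0, 1, 2, 3, 4),
                     min_app=0.85, min_occ=5.0, min_share=0.05, refine=True,
                     **spec_kwargs) -> SweepResult:
    """Fit-criteria sweep over group counts and polynomial orders.

    Fits every (n_groups, shared order) pair, reports loglik/AIC/BIC and the
    admission diagnostics, selects the best BIC among fits passing the
    APP/OCC/5%-share rules, then (optionally) refines per-group orders around
    the winner one group at a time.
    """
    rows, fits = [], {}
    for G in groups:
        for order in orders:
            spec = TrajectoryModelSpec(n_groups=G, poly_order=order, **spec_kwargs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_trajectory_model(data, spec)
            ok = _passes(fit, min_app, min_occ, min_share)
            fits[(G, order)] = fit
            rows.append({
                "n_groups": G, "poly_order": order, "loglik": fit.loglik,
                "aic": fit.aic, "bic": fit.bic, "min_app": float(np.nanmin(fit.app)),
                "min_occ": float(np.nanmin(fit.occ)), "min_share": float(fit.shares.min()),
                "converged": fit.converged, "admissible": ok,
            })
    report = pd.DataFrame(rows)
    admissible = report[report["admissible"]]
    if admissible.empty:
        return SweepResult(report=report, chosen=None, status="no admissible model")
    ix = admissible["bic"].idxmin()
    G = int(report.loc[ix, "n_groups"])
    best_fit = fits[(G, int(report.loc[ix, "poly_order"]))]

    if refine and G > 1:
        current = best_fit.spec.orders()
        for g in range(G):
            for o in orders:
                if o == current[g]:
                    continue
                trial = list(current)
                trial[g] = o
                spec = TrajectoryModelSpec(n_groups=G, poly_order=trial, **spec_kwargs)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_trajectory_model(data, spec)
                if fit.bic < best_fit.bic and _passes(fit, min_app, min_occ, min_share):
                    best_fit, current = fit, trial
    return SweepResult(report=report, chosen=best_fit, status="ok")
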