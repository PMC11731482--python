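"""Covariate-adjusted logistic AD/MCI risk models.

Logistic maximum-likelihood fits with cluster-robust (matched-set) sandwich
standard errors, odds-ratio tables, Hosmer-Lemeshow and link-test diagnostics,
correlated-AUROC comparison across nested covariate sets (DeLong), and
predictive margins with delta-method confidence intervals.

The sandwich covariance aggregates score contributions within clusters with no
small-sample degrees-of-freedom correction, so with singleton clusters it
coincides exactly with the heteroscedasticity-robust (HC0) estimator.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrices, build_design_matrices
from scipy import stats as sps
from scipy.special import expit

from .selection import aic_backward_select, SelectionResult

__all__ = ["RiskModelFit", "fit_logistic_cluster", "hosmer_lemeshow",
           "link_test", "auc_mann_whitney", "delong_auc_cov", "compare_aurocs",
           "predictive_margins", "backward_select_logistic"]


@dataclass
class RiskModelFit:
    formula: str
    terms: list
    table: pd.DataFrame            # term, beta, se, or, ci_low, ci_high, p
    cov_robust: np.ndarray
    params: np.ndarray
    llf: float
    aic: float
    pseudo_r2: float
    auroc: float
    n_clusters: int
    separation_flag: bool
    y: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)
    linpred: np.ndarray = field(repr=False, default=None)
    design_info: object = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    cluster: np.ndarray = field(repr=False, default=None)
    freq_weights: np.ndarray = field(repr=False, default=None)


def fit_logistic_cluster(data: pd.DataFrame, response: str, terms,
                         cluster=None, weights=None, z=1.959963984540054) -> RiskModelFit:
    """ML logistic fit with cluster-robust sandwich covariance.

    ``cluster`` is a column name or array of matched-set ids (default: each row
    its own cluster, which reduces the sandwich to HC0).  ``weights`` are
    optional frequency weights.  ORs and CIs come from the robust SEs.
    """
    terms = list(terms)
    formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
    ymat, X = dmatrices(formula, data, return_type="dataframe")
    design_info = X.design_info
    used_ix = X.index
    y = ymat.to_numpy().ravel()
    Xv = X.to_numpy()
    w = np.ones(len(y)) if weights is None else np.asarray(
        data.loc[used_ix, weights] if isinstance(weights, str) else weights, float)
    if cluster is None:
        groups = np.arange(len(y))
    else:
        groups = np.asarray(data.loc[used_ix, cluster] if isinstance(cluster, str) else cluster)

    model = sm.GLM(y, Xv, family=sm.families.Binomial(), freq_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200, tol=1e-12)
    beta = np.asarray(res.params)
    eta = Xv @ beta
    p = expit(eta)
    separation = bool(np.any(np.abs(beta) > 25) or
                      (np.all((p < 1e-8) | (p > 1 - 1e-8)) and len(np.unique(y)) == 2))
    if separation:
        warnings.warn("possible separation in logistic fit; estimates flagged")

    # sandwich: bread = (X' W X)^-1 with W = w p(1-p); meat = sum of cluster
    # score outer products; no df correction (singleton clusters == HC0)
    Wdiag = w * p * (1 - p)
    bread = np.linalg.inv(Xv.T @ (Xv * Wdiag[:, None]))
    scores = Xv * (w * (y - p))[:, None]
    gframe = pd.DataFrame(scores)
    gframe["_g"] = groups
    S = gframe.groupby("_g").sum().to_numpy()
    meat = S.T @ S
    cov = bread @ meat @ bread
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = 2 * sps.norm.sf(np.abs(zstat))
    table = pd.DataFrame({
        "term": design_info.column_names,
        "beta": beta, "se": se,
        "or": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
        "p": pvals,
    })
    llf = float(res.llf)
    k = Xv.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        llnull = float(sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                              freq_weights=w).fit().llf)
    pseudo = 1 - llf / llnull if llnull != 0 else np.nan
    return RiskModelFit(
        formula=formula, terms=terms, table=table, cov_robust=cov, params=beta,
        llf=llf, aic=-2 * llf + 2 * k, pseudo_r2=pseudo,
        auroc=auc_mann_whitney(y, p), n_clusters=len(np.unique(groups)),
        separation_flag=separation, y=y, fitted=p, linpred=eta,
        design_info=design_info, data=data.loc[used_ix], cluster=groups,
        freq_weights=w,
    )


def hosmer_lemeshow(y, p, g=10):
    """Hosmer-Lemeshow decile-of-risk goodness-of-fit chi-square.

    Groups by quantiles of predicted risk (duplicate edges merged); df is the
    effective group count minus 2.  Returns (statistic, df, p).
    """
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    bins = pd.qcut(pd.Series(p).rank(method="first"), q=g, duplicates="drop", labels=False)
    stat = 0.0
    g_eff = 0
    for b in np.unique(bins):
        m = bins == b
        o1, e1 = y[m].sum(), p[m].sum()
        o0, e0 = m.sum() - o1, m.sum() - e1
        if e1 <= 0 or e0 <= 0:
            continue
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        g_eff += 1
    df = max(g_eff - 2, 1)
    return float(stat), int(df), float(sps.chi2.sf(stat, df))


@dataclass
class LinkTestResult:
    ok: bool | None          # None when the refit is degenerate
    p_squared: float
    coef_squared: float


def link_test(fit: RiskModelFit, alpha=0.05) -> LinkTestResult:
    """Specification link test: refit the outcome on the linear predictor and
    its square; the model passes iff the squared term is non-significant.
    """
    xb = fit.linpred
    Z = np.column_stack([np.ones_like(xb), xb, xb ** 2])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(fit.y, Z).fit(disp=0, maxiter=100)
        if not np.all(np.isfinite(res.bse)):
            raise ValueError("degenerate")
        pv = float(res.pvalues[2])
        return LinkTestResult(ok=pv >= alpha, p_squared=pv, coef_squared=float(res.params[2]))
    except Exception:
        warnings.warn("link test refit degenerate (separation); flagged, not failed")
        return LinkTestResult(ok=None, p_squared=np.nan, coef_squared=np.nan)


def _midrank(x):
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def auc_mann_whitney(y, score):
    """AUC as the Mann-Whitney U statistic divided by n1*n0 (midranks for ties)."""
    y = np.asarray(y).astype(bool)
    score = np.asarray(score, float)
    m, n = y.sum(), (~y).sum()
    if m == 0 or n == 0:
        raise ValueError("need both cases and controls")
    r = _midrank(score)
    return float((r[y].sum() - m * (m + 1) / 2) / (m * n))


def delong_auc_cov(y, scores):
    """DeLong AUCs and covariance matrix for k correlated ROC curves.

    ``scores`` has shape (k, n).  Uses the fast midrank formulation.
    """
    y = np.asarray(y).astype(bool)
    scores = np.atleast_2d(np.asarray(scores, float))
    k, n_all = scores.shape
    m, n = int(y.sum()), int((~y).sum())
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for i in range(k):
        x, z = scores[i, y], scores[i, ~y]
        tx = _midrank(x)
        tz = _midrank(z)
        t = _midrank(np.concatenate([x, z]))
        aucs[i] = (t[:m].sum() - m * (m + 1) / 2) / (m * n)
        v10[i] = (t[:m] - tx) / n
        v01[i] = 1.0 - (t[m:] - tz) / m
    s10 = np.cov(v10) if m > 1 else np.zeros((k, k))
    s01 = np.cov(v01) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def compare_aurocs(y, scores, labels=None, alpha=0.05):
    """Equality test of k correlated AUROCs (DeLong) with Bonferroni pairwise P.

    Returns a dict: per-model AUCs, the global chi-square equality test
    (contrasting successive curves, df = rank of the contrast covariance), and
    a pairwise table with Bonferroni-adjusted P values.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    k = scores.shape[0]
    labels = list(labels) if labels is not None else [f"model{i+1}" for i in range(k)]
    aucs, cov = delong_auc_cov(y, scores)
    if k == 1:
        return {"labels": labels, "aucs": aucs, "chi2": 0.0, "df": 0, "p_equality": 1.0,
                "pairwise": pd.DataFrame()}
    L = np.diff(np.eye(k), axis=0)
    d = L @ aucs
    V = L @ cov @ L.T
    rank = np.linalg.matrix_rank(V, tol=1e-12)
    if rank == 0:
        chi2, pval = 0.0, 1.0
    else:
        chi2 = float(d @ np.linalg.pinv(V, rcond=1e-12) @ d)
        pval = float(sps.chi2.sf(chi2, rank))
    rows = []
    n_pairs = k * (k - 1) // 2
    for i, j in itertools.combinations(range(k), 2):
        var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
        diff = aucs[i] - aucs[j]
        if var <= 1e-16:
            p_ij = 1.0 if abs(diff) < 1e-12 else 0.0
        else:
            p_ij = 2 * sps.norm.sf(abs(diff) / np.sqrt(var))
        rows.append({"model_a": labels[i], "model_b": labels[j],
                     "auc_a": aucs[i], "auc_b": aucs[j], "diff": diff,
                     "p": p_ij, "p_bonferroni": min(1.0, n_pairs * p_ij)})
    return {"labels": labels, "aucs": aucs, "chi2": chi2, "df": int(rank),
            "p_equality": pval, "pairwise": pd.DataFrame(rows)}


def predictive_margins(fit: RiskModelFit, grid: dict, mode="average",
                       z=1.959963984540054) -> pd.DataFrame:
    """Predicted-probability margins over a covariate grid.

    ``grid`` maps covariate names to value sequences; margins are computed at
    the cartesian product.  ``mode='average'`` averages predictions over the
    sample with the grid covariates fixed; ``mode='at_means'`` predicts at the
    design-matrix column means (other covariates at mean values).  Delta-method
    CIs from the cluster-robust covariance, clamped to [0, 1].
    """
    missing = [c for c in grid if c not in fit.data.columns]
    if missing:
        raise ValueError(f"grid covariates not in model data: {missing}")
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(np.asarray(grid[k]).tolist() for k in keys)):
        mod = fit.data.copy()
        for kname, val in zip(keys, combo):
            mod[kname] = val
        (X,) = build_design_matrices([fit.design_info], mod)
        X = np.asarray(X)
        if mode == "at_means":
            X = X.mean(axis=0, keepdims=True)
        elif mode != "average":
            raise ValueError("mode must be 'average' or 'at_means'")
        p = expit(X @ fit.params)
        margin = float(p.mean())
        grad = (p * (1 - p))[:, None] * X
        gbar = grad.mean(axis=0)
        var = float(gbar @ fit.cov_robust @ gbar)
        se = np.sqrt(max(var, 0.0))
        row = dict(zip(keys, combo))
        row.update({"margin": margin, "se": se,
                    "ci_low": max(margin - z * se, 0.0),
                    "ci_high": min(margin + z * se, 1.0)})
        rows.append(row)
    return pd.DataFrame(rows)


def backward_select_logistic(data, response, candidates, locked=(),
                             cluster=None, weights=None) -> SelectionResult:
    """AIC backward selection for the cluster-robust logistic risk models."""
    def fit_fn(terms):
        return fit_logistic_cluster(data, response, terms,
                                    cluster=cluster, weights=weights)
    return aic_backward_select(fit_fn, list(candidates), locked=list(locked))
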