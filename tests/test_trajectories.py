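import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.integrate import quad
from scipy.special import logsumexp
from scipy.stats import norm

from lipidtraj import trajectories as tj
from conftest import hdl_series


class TestCensoredNormalLoglik:
    def test_interior_mode_equals_normal_density(self):
        ll = tj.censored_normal_loglik(5.0, 5.0, 2.0, -1e6, 1e6)
        assert ll == pytest.approx(-np.log(2.0 * np.sqrt(2 * np.pi)), abs=1e-12)

    def test_boundary_value_gets_tail_mass(self):
        ll = tj.censored_normal_loglik(0.0, 0.0, 1.0, 0.0, 10.0)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_total_mass_one_by_quadrature(self):
        mu, sigma, lo, hi = 1.3, 2.1, -2.0, 4.0
        interior, _ = quad(lambda v: np.exp(
            tj.censored_normal_loglik(v, mu, sigma, lo, hi)), lo + 1e-12, hi - 1e-12)
        mass = (interior
                + np.exp(tj.censored_normal_loglik(lo, mu, sigma, lo, hi))
                + np.exp(tj.censored_normal_loglik(hi, mu, sigma, lo, hi)))
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            tj.censored_normal_loglik(0.0, 0.0, 0.0)


class TestOcc:
    def test_chance_assignment_gives_one(self):
        np.testing.assert_allclose(tj.compute_occ([0.3], [0.3]), [1.0])

    def test_printed_arithmetic_example(self):
        occ = tj.compute_occ([0.85], [0.5])
        assert occ[0] == pytest.approx(0.85 / 0.15, abs=1e-10)
        assert occ[0] == pytest.approx(5.667, abs=1e-3)

    def test_perfect_assignment_gives_inf(self):
        assert np.isinf(tj.compute_occ([1.0], [0.4])[0])


class TestSingleGroupFit:
    def test_order_zero_intercept_is_sample_mean_on_shared_schedule(self, rng):
        rows = []
        for i in range(30):
            for yr in range(-8, 1, 2):
                rows.append({"subject_id": i, "rel_year": yr,
                             "value": rng.normal(60, 5)})
        d = pd.DataFrame(rows)
        spec = tj.TrajectoryModelSpec(n_groups=1, poly_order=0,
                                      include_med_covariate=False)
        fit = tj.fit_trajectory_model(d, spec)
        assert fit.coefs[0][0] == pytest.approx(d["value"].mean(), abs=1e-8)
        assert fit.app[0] == pytest.approx(1.0)
        assert np.isinf(fit.occ[0])


class TestParameterRecovery:
    def test_two_flat_groups_recovered(self, rng):
        rows, truth = [], {}
        for i in range(400):
            g = int(rng.random() < 0.5)
            truth[i] = g + 1
            for yr in rng.choice(np.arange(-10, 1), 6, replace=False):
                rows.append({"subject_id": i, "rel_year": int(yr),
                             "value": rng.normal([40, 80][g], 3.0)})
        d = pd.DataFrame(rows)
        spec = tj.TrajectoryModelSpec(n_groups=2, poly_order=0, n_starts=5,
                                      include_med_covariate=False, seed=0)
        fit = tj.fit_trajectory_model(d, spec)
        means = [c[0] for c in fit.coefs]
        assert means[0] == pytest.approx(40, abs=1.5)
        assert means[1] == pytest.approx(80, abs=1.5)
        assert fit.pi[0] == pytest.approx(0.5, abs=0.05)
        truth_ser = pd.Series(truth)
        acc = (fit.assignments == truth_ser.loc[fit.assignments.index]).mean()
        assert acc >= 0.99

    def test_tiny_instance_matches_direct_optimizer_oracle(self, rng):
        rows = []
        for i in range(6):
            mu = 40 if i < 3 else 70
            for yr in (-6, -3, 0):
                rows.append({"subject_id": i, "rel_year": yr,
                             "value": rng.normal(mu, 2.0)})
        d = pd.DataFrame(rows)
        spec = tj.TrajectoryModelSpec(n_groups=2, poly_order=0, n_starts=8,
                                      include_med_covariate=False, seed=1)
        fit = tj.fit_trajectory_model(d, spec)

        # independent oracle: direct maximization of the mixture loglik
        y = d["value"].to_numpy()
        idx = d["subject_id"].to_numpy()
        subj = np.unique(idx)

        def negll(theta):
            m1, m2, logsig, a = theta
            pi1 = 1 / (1 + np.exp(-a))
            sig = np.exp(logsig)
            sl = np.stack([
                np.array([norm.logpdf(y[idx == s], m, sig).sum() for s in subj])
                for m in (m1, m2)], axis=1)
            return -logsumexp(sl + np.log([pi1, 1 - pi1]), axis=1).sum()

        best = min(
            (optimize.minimize(negll, x0, method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10,
                                        "maxiter": 5000})
             for x0 in ([40, 70, 1.0, 0.0], [45, 65, 0.5, 0.4])),
            key=lambda r: r.fun)
        assert fit.loglik == pytest.approx(-best.fun, abs=1e-4)


class TestSweep:
    def test_three_groups_selected_with_admission_rules(self, three_group_hdl_cohort):
        d = hdl_series(three_group_hdl_cohort)
        sweep = tj.sweep_and_select(d, groups=(1, 2, 3, 4), orders=(0, 1),
                                    n_starts=5, seed=0)
        assert sweep.status == "ok"
        fit = sweep.chosen
        assert len(fit.pi) == 3
        assert fit.app.min() >= 0.85
        assert fit.occ.min() >= 5.0
        # two-group BIC must be worse than the chosen three-group BIC
        rep = sweep.report
        bic2 = rep[(rep.n_groups == 2)]["bic"].min()
        assert fit.bic < bic2

    def test_small_group_rejected_by_share_rule(self, rng):
        # 3% of subjects sit in a far-out group: 2-group fits capture it but
        # fail the 5% share rule; an admissible 1-group fit is returned instead
        rows = []
        for i in range(200):
            mu = 200 if i >= 6 else 600
            for yr in (-8, -5, -2, 0):
                rows.append({"subject_id": i, "rel_year": yr,
                             "value": rng.normal(mu, 5)})
        d = pd.DataFrame(rows)
        sweep = tj.sweep_and_select(d, groups=(1, 2), orders=(0,), n_starts=4,
                                    include_med_covariate=False, seed=0)
        rep = sweep.report.set_index("n_groups")
        assert not rep.loc[2, "admissible"]
        assert rep.loc[2, "min_share"] < 0.05
        assert rep.loc[2, "bic"] < rep.loc[1, "bic"]   # BIC-best yet rejected
        assert len(sweep.chosen.pi) == 1

    def test_single_group_data_selects_one_group(self, rng):
        rows = [{"subject_id": i, "rel_year": yr, "value": rng.normal(55, 4)}
                for i in range(150) for yr in (-9, -6, -3, 0)]
        sweep = tj.sweep_and_select(pd.DataFrame(rows), groups=(1, 2), orders=(0,),
                                    n_starts=4, include_med_covariate=False, seed=0)
        assert len(sweep.chosen.pi) == 1
        assert sweep.chosen.app[0] == pytest.approx(1.0)
        assert np.isinf(sweep.chosen.occ[0])

    def test_no_admissible_model_status(self, rng):
        # two heavily overlapping groups: no multi-group fit passes APP/OCC and
        # the 1-group spec is excluded from the grid
        rows = [{"subject_id": i, "rel_year": yr,
                 "value": rng.normal(55 + 0.5 * (i % 2), 6)}
                for i in range(100) for yr in (-9, -6, -3, 0)]
        sweep = tj.sweep_and_select(pd.DataFrame(rows), groups=(2, 3), orders=(0,),
                                    n_starts=3, include_med_covariate=False, seed=0)
        assert sweep.status == "no admissible model"
        assert sweep.chosen is None


class TestFitInvariants:
    def test_posteriors_rows_sum_to_one_and_labels_ascend(self, three_group_hdl_cohort):
        d = hdl_series(three_group_hdl_cohort)
        spec = tj.TrajectoryModelSpec(n_groups=3, poly_order=0, n_starts=4, seed=0)
        fit = tj.fit_trajectory_model(d, spec)
        post = fit.posteriors[["g1", "g2", "g3"]].to_numpy()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
        assert fit.shares.sum() == pytest.approx(1.0)
        year0 = [c[0] for c in fit.coefs]
        assert year0 == sorted(year0)

    def test_wide_bounds_agree_with_uncensored_fit(self, three_group_hdl_cohort):
        d = hdl_series(three_group_hdl_cohort).head(600)
        base = tj.TrajectoryModelSpec(n_groups=2, poly_order=0, n_starts=3, seed=0)
        wide = tj.TrajectoryModelSpec(n_groups=2, poly_order=0, n_starts=3, seed=0,
                                      y_min=-1e4, y_max=1e4)
        f1 = tj.fit_trajectory_model(d, base)
        f2 = tj.fit_trajectory_model(d, wide)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)

    def test_censoring_at_data_bounds_runs_and_flags_nothing(self, rng):
        rows = [{"subject_id": i, "rel_year": yr, "value": rng.normal(60, 5)}
                for i in range(40) for yr in (-8, -4, 0)]
        d = pd.DataFrame(rows)
        lo, hi = d["value"].min(), d["value"].max()
        spec = tj.TrajectoryModelSpec(n_groups=1, poly_order=0, y_min=lo, y_max=hi,
                                      include_med_covariate=False)
        fit = tj.fit_trajectory_model(d, spec)
        assert np.isfinite(fit.loglik)
        assert fit.converged
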