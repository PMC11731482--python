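import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

from lipidtraj import risk


def _two_by_two(a, b, c, d):
    """Exposed cases a, unexposed cases b, exposed controls c, unexposed d."""
    return pd.DataFrame({
        "y": [1] * (a + b) + [0] * (c + d),
        "x": [1] * a + [0] * b + [1] * c + [0] * d,
    })


class TestClusterLogistic:
    def test_two_by_two_or_is_cross_product_ratio(self):
        df = _two_by_two(56, 159, 83, 400)
        fit = risk.fit_logistic_cluster(df, "y", ["x"])
        target = (56 * 400) / (83 * 159)
        assert abs(fit.table.set_index("term").loc["x", "or"] - target) < 1e-10

    def test_null_predictor_ci_covers_one(self, rng):
        covered = 0
        reps = 40
        for _ in range(reps):
            df = pd.DataFrame({"x": rng.normal(size=300),
                               "y": (rng.random(300) < 0.4).astype(int)})
            t = risk.fit_logistic_cluster(df, "y", ["x"]).table.set_index("term")
            covered += t.loc["x", "ci_low"] <= 1.0 <= t.loc["x", "ci_high"]
        assert covered >= int(0.85 * reps)

    def test_singleton_clusters_equal_hc0(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=200)})
        df["y"] = (rng.random(200) < 0.35).astype(int)
        fit = risk.fit_logistic_cluster(df, "y", ["x"])
        ref = sm.GLM(df["y"], sm.add_constant(df["x"]),
                     family=sm.families.Binomial()).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.table["se"].to_numpy(),
                                   ref.bse.to_numpy(), atol=1e-10)

    def test_within_cluster_correlation_widens_se(self, rng):
        # duplicate every row into a 2-member cluster: scores double per
        # cluster, so cluster-robust SE must exceed the naive singleton SE
        base = pd.DataFrame({"x": rng.normal(size=150)})
        base["y"] = (rng.random(150) < 1 / (1 + np.exp(-base["x"]))).astype(int)
        dup = pd.concat([base, base], ignore_index=True)
        dup["cl"] = list(range(150)) * 2
        f_cl = risk.fit_logistic_cluster(dup, "y", ["x"], cluster="cl")
        f_no = risk.fit_logistic_cluster(dup, "y", ["x"])
        assert (f_cl.table["se"] > f_no.table["se"]).all()

    def test_separation_flagged(self):
        df = pd.DataFrame({"x": np.r_[np.ones(20), np.zeros(20)],
                           "y": np.r_[np.ones(20), np.zeros(20)].astype(int)})
        with pytest.warns(UserWarning, match="separation"):
            fit = risk.fit_logistic_cluster(df, "y", ["x"])
        assert fit.separation_flag


class TestHosmerLemeshow:
    def test_df_is_groups_minus_two(self, rng):
        y = (rng.random(500) < 0.3).astype(int)
        p = np.clip(rng.random(500), 0.01, 0.99)
        _, df, _ = risk.hosmer_lemeshow(y, p, g=10)
        assert df == 8

    def test_saturated_grouped_model_statistic_near_zero(self):
        # predicted probability equals the observed group fraction exactly
        y = np.array([1, 0, 0, 0, 0] * 20 + [1, 1, 1, 0, 0] * 20)
        p = np.array([0.2] * 100 + [0.6] * 100)
        stat, _, _ = risk.hosmer_lemeshow(y, p, g=2)
        assert stat == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_computed_decile_table(self, rng):
        y = (rng.random(60) < 0.4).astype(int)
        p = np.sort(rng.uniform(0.05, 0.95, 60))
        stat, df, _ = risk.hosmer_lemeshow(y, p, g=3)
        manual = 0.0
        for block in np.split(np.arange(60), 3):
            o1, e1 = y[block].sum(), p[block].sum()
            n = len(block)
            manual += (o1 - e1) ** 2 / e1 + ((n - o1) - (n - e1)) ** 2 / (n - e1)
        assert stat == pytest.approx(manual, abs=1e-10)


class TestLinkTest:
    def test_correct_specification_passes_most_replicates(self, rng):
        passes = 0
        reps = 20
        for _ in range(reps):
            x = rng.normal(size=400)
            y = (rng.random(400) < 1 / (1 + np.exp(-(0.2 + x)))).astype(int)
            fit = risk.fit_logistic_cluster(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
            passes += bool(risk.link_test(fit).ok)
        assert passes >= int(0.9 * reps)

    def test_omitted_quadratic_fails(self, rng):
        x = rng.normal(size=3000)
        lp = -1 + x + 1.5 * x ** 2
        y = (rng.random(3000) < 1 / (1 + np.exp(-lp))).astype(int)
        fit = risk.fit_logistic_cluster(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert risk.link_test(fit).ok is False

    def test_separated_input_flagged_without_crash(self):
        df = pd.DataFrame({"x": np.r_[np.ones(15), np.zeros(15)],
                           "y": np.r_[np.ones(15), np.zeros(15)].astype(int)})
        with pytest.warns(UserWarning):
            fit = risk.fit_logistic_cluster(df, "y", ["x"])
            out = risk.link_test(fit)
        assert out.ok is None


class TestAuroc:
    def test_auc_equals_mann_whitney_on_toy(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        s = np.array([0.2, 0.3, 0.5, 0.9, 0.4, 0.4])
        u = mannwhitneyu(s[y == 1], s[y == 0]).statistic
        assert risk.auc_mann_whitney(y, s) == pytest.approx(u / 9, abs=1e-12)

    def test_model_compared_with_itself(self, rng):
        y = (rng.random(80) < 0.4).astype(int)
        s = rng.normal(size=80)
        out = risk.compare_aurocs(y, np.vstack([s, s]))
        assert out["p_equality"] == 1.0
        assert out["pairwise"]["diff"].iloc[0] == 0.0

    def test_informative_beats_noise_with_small_p(self, rng):
        y = (rng.random(400) < 0.5).astype(int)
        good = y + rng.normal(0, 0.7, 400)
        noise = rng.normal(size=400)
        out = risk.compare_aurocs(y, np.vstack([good, noise]), labels=["g", "n"])
        assert out["aucs"][0] > out["aucs"][1]
        assert out["p_equality"] < 0.001
        assert out["pairwise"]["p_bonferroni"].iloc[0] >= out["pairwise"]["p"].iloc[0]


class TestMargins:
    def _fit(self, rng, n=300):
        df = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        lp = -0.5 + 0.8 * df["x"]
        df["y"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        return df, risk.fit_logistic_cluster(df, "y", ["x", "z"])

    def test_intercept_only_margin_is_prevalence(self, rng):
        df = pd.DataFrame({"y": (rng.random(200) < 0.3).astype(int),
                           "g": rng.normal(size=200)})
        fit = risk.fit_logistic_cluster(df, "y", [])
        out = risk.predictive_margins(fit, {"g": [-1.0, 0.0, 1.0]})
        np.testing.assert_allclose(out["margin"], df["y"].mean(), atol=1e-8)

    def test_margin_monotone_in_positive_coefficient(self, rng):
        _, fit = self._fit(rng)
        out = risk.predictive_margins(fit, {"x": np.linspace(-2, 2, 9)})
        assert np.all(np.diff(out["margin"]) > 0)
        assert out["ci_low"].between(0, 1).all()
        assert out["ci_high"].between(0, 1).all()

    def test_delta_ci_close_to_cluster_bootstrap(self, rng):
        df, fit = self._fit(rng, n=250)
        out = risk.predictive_margins(fit, {"x": [0.5]})
        boots = []
        for _ in range(400):
            bs = df.sample(frac=1, replace=True, random_state=rng.integers(2**31))
            bfit = risk.fit_logistic_cluster(bs, "y", ["x", "z"])
            boots.append(risk.predictive_margins(bfit, {"x": [0.5]})["margin"][0])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        w_delta = out["ci_high"][0] - out["ci_low"][0]
        w_boot = hi - lo
        assert abs(w_delta - w_boot) / w_boot < 0.15

    def test_unknown_grid_covariate_rejected(self, rng):
        _, fit = self._fit(rng)
        with pytest.raises(ValueError, match="nope"):
            risk.predictive_margins(fit, {"nope": [0]})
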