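"""Inferential toolkit against independent formula/brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neogyri.stats import (
    ancova_group_test,
    bh_fdr,
    normality_screen,
    partial_spearman,
    pearson_corr,
    welch_ttest,
)

from .oracles import bh_oracle, pearson_oracle, pooled_t_oracle, spearman_oracle, welch_t_oracle

DATASETS = [
    ([1, 2, 3, 4, 5], [2, 3, 4, 5, 6]),
    ([0.3, 1.2, -0.7, 2.2, 0.1, 0.5], [1.0, 0.2, 0.4]),
    ([10.0, 11.5, 9.8, 10.2, 12.0, 11.1, 10.7], [9.0, 9.5, 8.8, 10.1]),
]


class TestWelch:
    @pytest.mark.parametrize("a,b", DATASETS)
    def test_matches_hand_formula(self, a, b):
        res = welch_ttest(a, b)
        t, df, p = welch_t_oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-8)
        assert res.p_raw == pytest.approx(p, abs=1e-10)

    def test_identical_samples(self):
        res = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 3.0, 3.5]
        r1, r2 = welch_ttest(a, b), welch_ttest(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_degenerate_constant_samples(self):
        res = welch_ttest([2.0, 2.0], [2.0, 2.0])
        assert res.p_raw == 1.0
        with pytest.raises(ValueError):
            welch_ttest([2.0, 2.0], [3.0, 3.0])

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])


class TestAncova:
    def test_no_covariates_reduces_to_anova(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "y": rng.normal(size=40),
            "g": ["a"] * 20 + ["b"] * 20,
        })
        res = ancova_group_test(df, "y", "g")
        t = pooled_t_oracle(df.y[df.g == "a"], df.y[df.g == "b"])
        assert res.statistic == pytest.approx(t**2, abs=1e-8)

    def test_matches_statsmodels_formula_ancova(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "y": rng.normal(size=60),
            "g": rng.choice(["a", "b", "c"], 60),
            "x": rng.normal(size=60),
        })
        res = ancova_group_test(df, "y", "g", ["x"])
        full = smf.ols("y ~ x + C(g)", df).fit()
        red = smf.ols("y ~ x", df).fit()
        tab = anova_lm(red, full)
        assert res.statistic == pytest.approx(float(tab["F"][1]), abs=1e-8)
        assert res.p_raw == pytest.approx(float(tab["Pr(>F)"][1]), abs=1e-10)

    def test_type_one_error_calibrated(self):
        # null outcome, n=500 per rep; rejection rate at alpha=.05 in [.04,.06]
        # (4000 reps keep the Monte-Carlo error of the rate itself at ~0.003)
        rng = np.random.default_rng(42)
        hits = 0
        reps = 4000
        g = np.array(["a"] * 250 + ["b"] * 250)
        for _ in range(reps):
            df = pd.DataFrame({"y": rng.normal(size=500), "g": g,
                               "x": rng.normal(size=500)})
            hits += ancova_group_test(df, "y", "g", ["x"]).p_raw < 0.05
        assert 0.04 <= hits / reps <= 0.06

    def test_outcome_as_covariate_degenerates(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(size=30),
                           "g": ["a", "b"] * 15})
        df["x"] = df["y"]
        with pytest.warns(UserWarning, match="F = 0"):
            res = ancova_group_test(df, "y", "g", ["x"])
        assert res.statistic == 0.0

    def test_rank_deficiency_names_aliased(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.normal(size=30), "g": ["a", "b"] * 15,
                           "x1": rng.normal(size=30)})
        df["x2"] = 2 * df["x1"]
        with pytest.raises(ValueError, match="x2"):
            ancova_group_test(df, "y", "g", ["x1", "x2"])


class TestPearson:
    def test_perfect_and_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_corr(x, x).statistic == pytest.approx(1.0)
        res = pearson_corr(x, -2 * x + 3)
        assert res.statistic == pytest.approx(-1.0)
        assert res.effect["r_squared"] == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        res = pearson_corr(x, y)
        r, p = pearson_oracle(x, y)
        assert res.statistic == pytest.approx(r, abs=1e-12)
        assert res.p_raw == pytest.approx(p, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialSpearman:
    def test_reduces_to_plain_spearman(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = partial_spearman(x, y)
        assert res.statistic == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50),
                           "c1": rng.normal(size=50), "c2": rng.normal(size=50)})
        res = partial_spearman(df.x, df.y, df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p_raw == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=25), rng.normal(size=25)
        c = rng.normal(size=25)
        base = partial_spearman(x, y, c).statistic
        warped = partial_spearman(x, np.exp(y), c).statistic
        assert warped == pytest.approx(base, abs=1e-12)

    def test_shared_covariate_partialled_out(self):
        rng = np.random.default_rng(7)
        c = rng.normal(size=500)
        x = c + rng.normal(size=500)
        y = c + rng.normal(size=500)
        assert abs(partial_spearman(x, y, c).statistic) < 0.1

    def test_constant_after_ranking_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman([1.0] * 10, np.arange(10.0))


class TestBHFDR:
    def test_textbook_example_all_point_oh_five(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(adj, 0.05, atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.42])[0] == pytest.approx(0.42)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_and_dominates_raw(self, ps):
        adj = bh_fdr(ps)
        np.testing.assert_allclose(adj, bh_oracle(ps), atol=1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestNormalityScreen:
    def test_null_rejection_rate(self):
        rng = np.random.default_rng(0)
        hits = sum(
            normality_screen(rng.normal(size=200)).p_raw < 0.05 for _ in range(500)
        )
        assert 0.03 <= hits / 500 <= 0.07

    def test_power_on_lognormal(self):
        rng = np.random.default_rng(1)
        hits = sum(
            normality_screen(rng.lognormal(size=200)).p_raw < 0.01 for _ in range(100)
        )
        assert hits >= 95

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_screen([1.0] * 10)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])
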