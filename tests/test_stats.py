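"""Regression, ANOVA and reproducibility statistics against hand/brute oracles."""

import numpy as np
import pandas as pd
import pytest

from aortastrain.stats import (
    PairedMeasurements,
    anova_oneway,
    bland_altman,
    coefficient_of_variation,
    icc,
    linear_regression,
    ttest_2sample,
)


class TestLinearRegression:
    def test_exact_line_recovers_slope_and_unit_r2(self):
        x = np.arange(10.0)
        r = linear_regression(2 * x, x)
        assert r.params.iloc[1] == pytest.approx(2.0)
        assert r.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(50)
        X = rng.normal(size=(50, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=50)
        r = linear_regression(y, X)
        D = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(r.params.to_numpy(), beta, atol=1e-10)
        resid = y - D @ r.params.to_numpy()
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert r.r2 == pytest.approx(1 - np.sum(resid**2) / ss_tot, abs=1e-10)
        assert r.r2_adj <= r.r2

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(51)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        r = linear_regression(y, X)
        D = np.column_stack([np.ones(40), X])
        resid = y - D @ r.params.to_numpy()
        assert np.abs(D.T @ resid).max() < 1e-9

    def test_duplicated_column_raises_naming_it(self):
        rng = np.random.default_rng(52)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=30)})
        with pytest.raises(ValueError, match="collinear.*'a'.*'b'"):
            linear_regression(rng.normal(size=30), X)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression(np.arange(10.0), np.ones(10))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            linear_regression(np.arange(3.0), np.random.default_rng(0).normal(size=(3, 2)))


class TestBlandAltman:
    def test_identical_measurements(self):
        pm = PairedMeasurements(np.arange(5.0) + 1, np.arange(5.0) + 1)
        ba = bland_altman(pm)
        assert ba["bias"] == 0.0 and ba["loa_lower"] == 0.0 == ba["loa_upper"]

    def test_alternating_differences_hand_values(self):
        pm = PairedMeasurements(np.array([1.0, 0, 1, 0]), np.array([0.0, 1, 0, 1]))
        ba = bland_altman(pm)
        assert ba["bias"] == pytest.approx(0.0)
        assert ba["sd_diff"] == pytest.approx(1.1547, abs=1e-4)
        assert ba["loa_upper"] == pytest.approx(1.96 * 1.1547005, abs=1e-4)

    def test_constant_offset(self):
        a = np.array([3.0, 5.0, 9.0])
        pm = PairedMeasurements(a + 2, a)
        ba = bland_altman(pm)
        assert ba["bias"] == pytest.approx(2.0)
        assert ba["loa_lower"] == pytest.approx(2.0) == pytest.approx(ba["loa_upper"])

    def test_bias_equals_difference_of_means(self):
        rng = np.random.default_rng(3)
        pm = PairedMeasurements(rng.normal(10, 2, 30), rng.normal(9, 2, 30))
        assert bland_altman(pm)["bias"] == pytest.approx(pm.a.mean() - pm.b.mean())


class TestCoefficientOfVariation:
    def test_identical_measurements_zero(self):
        pm = PairedMeasurements(np.array([4.0, 5, 6]), np.array([4.0, 5, 6]))
        assert coefficient_of_variation(pm) == 0.0

    def test_hand_computed_rms_value(self):
        pm = PairedMeasurements(np.array([10.0, 8, 6]), np.array([11.0, 7, 6]))
        # within-subject SD = sqrt((1+1+0)/(2*3)) = 0.57735; grand mean = 8
        assert coefficient_of_variation(pm) == pytest.approx(7.2169, abs=1e-3)

    def test_scale_invariance(self):
        pm = PairedMeasurements(np.array([10.0, 8, 6]), np.array([11.0, 7, 6]))
        pm2 = PairedMeasurements(2 * pm.a, 2 * pm.b)
        assert coefficient_of_variation(pm2) == pytest.approx(coefficient_of_variation(pm))

    def test_sd_diff_variant(self):
        pm = PairedMeasurements(np.array([10.0, 8, 6]), np.array([11.0, 7, 6]))
        d = pm.a - pm.b
        expected = 100 * d.std(ddof=1) / 8.0
        assert coefficient_of_variation(pm, method="sd_diff") == pytest.approx(expected)

    def test_zero_mean_rejected(self):
        pm = PairedMeasurements(np.array([1.0, -1, 0]), np.array([-1.0, 1, 0]))
        with pytest.raises(ValueError, match="grand mean"):
            coefficient_of_variation(pm)


class TestICC:
    def test_perfect_agreement_is_one(self):
        a = np.array([3.0, 5, 9, 12, 7])
        v, (lo, hi) = icc(PairedMeasurements(a, a.copy()))
        assert v == pytest.approx(1.0)
        assert hi == pytest.approx(1.0)

    def test_variance_ratio_construction_gives_half(self):
        """a = s + e1, b = s + e2 with Var(s) = Var(e): population ICC is
        exactly subject variance over total, i.e. 0.5."""
        rng = np.random.default_rng(123)
        n = 3000
        s = rng.normal(0, 1, n)
        a = s + rng.normal(0, 1, n)
        b = s + rng.normal(0, 1, n)
        v, _ = icc(PairedMeasurements(a, b))
        assert v == pytest.approx(0.5, abs=0.08)

    def test_rater_swap_symmetry(self):
        rng = np.random.default_rng(8)
        a = rng.normal(10, 2, 25)
        b = a + rng.normal(0, 1, 25)
        v1, ci1 = icc(PairedMeasurements(a, b))
        v2, ci2 = icc(PairedMeasurements(b, a))
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert ci1 == pytest.approx(ci2, abs=1e-12)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(9)
        a = rng.normal(10, 2, 25)
        b = a + rng.normal(0, 1, 25)
        v1, _ = icc(PairedMeasurements(a, b))
        v2, _ = icc(PairedMeasurements(a + 100, b + 100))
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_matches_pingouin_two_way_random_absolute(self):
        """Independent implementation in pingouin is the oracle."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        a = rng.normal(10, 2, 40)
        b = a + rng.normal(0, 0.8, 40)
        v, (lo, hi) = icc(PairedMeasurements(a, b))
        df = pd.DataFrame({"subj": np.tile(np.arange(40), 2),
                           "rater": np.repeat([0, 1], 40),
                           "y": np.concatenate([a, b])})
        res = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
        row = res[res["Type"] == "ICC(A,1)"].iloc[0] if (res["Type"] == "ICC(A,1)").any() \
            else res[res["Type"] == "ICC2"].iloc[0]
        assert v == pytest.approx(row["ICC"], abs=1e-9)
        ci_col = "CI95" if "CI95" in res.columns else "CI95%"
        np.testing.assert_allclose([lo, hi], list(row[ci_col]), atol=0.01)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc(PairedMeasurements(np.full(5, 3.0), np.full(5, 3.0)))


class TestANOVA:
    def test_identical_groups_f_zero_p_one(self):
        g = np.array([1.0, 2, 3])
        f, p = anova_oneway([g, g.copy()])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_f_for_two_small_groups(self):
        f, p = anova_oneway([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        assert f == pytest.approx(13.5)

    def test_separated_groups_reach_high_significance(self):
        rng = np.random.default_rng(21)
        groups = [rng.normal(3 * i, 1.0, 20) for i in range(4)]
        f, p = anova_oneway(groups)
        assert p < 1e-4

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError, match="n=1"):
            anova_oneway([np.array([1.0, 2]), np.array([3.0])])

    def test_matches_scipy_on_random_groups(self):
        from scipy import stats as sps

        rng = np.random.default_rng(22)
        groups = [rng.normal(0, 1, 15) for _ in range(3)]
        f, p = anova_oneway(groups)
        f2, p2 = sps.f_oneway(*groups)
        assert f == pytest.approx(float(f2)) and p == pytest.approx(float(p2))


class TestPairsValidation:
    @pytest.mark.parametrize("a, b", [
        (np.arange(2.0), np.arange(2.0)),
        (np.arange(4.0), np.arange(5.0)),
        (np.array([1.0, np.nan, 2]), np.arange(3.0)),
    ])
    def test_bad_pairs_rejected(self, a, b):
        with pytest.raises(ValueError):
            PairedMeasurements(a, b)


def test_two_sample_ttest_matches_scipy():
    from scipy import stats as sps

    rng = np.random.default_rng(30)
    a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
    t, p = ttest_2sample(a, b)
    t2, p2 = sps.ttest_ind(a, b)
    assert t == pytest.approx(float(t2)) and p == pytest.approx(float(p2))
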