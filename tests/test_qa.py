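"""Stability, sensitivity, repeatability and success-rate statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sonoqa as sq


class TestPercentDeviation:
    @pytest.mark.parametrize(
        "measured,baseline,expected",
        [(110, 100, 10.0), (100, 100, 0.0), (90, 100, -10.0)],
    )
    def test_signed_percent_error(self, measured, baseline, expected):
        assert sq.percent_deviation(measured, baseline) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sq.percent_deviation(1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_self_deviation_is_zero(self, x):
        assert sq.percent_deviation(x, x) == 0.0

    def test_not_antisymmetric(self):
        # percent error is baseline-referenced, not symmetric
        assert sq.percent_deviation(110, 100) != -sq.percent_deviation(100, 110)


class TestStabilityVerdict:
    @pytest.mark.parametrize(
        "dev,verdict",
        [(9.9, "pass"), (10.0, "pass"), (-10.0, "pass"), (-10.4, "fail"), (15.6, "fail")],
    )
    def test_inclusive_ten_percent_threshold(self, dev, verdict):
        assert sq.stability_verdict(dev) == verdict

    def test_stability_test_object(self):
        t = sq.stability_test("contrast_9L", 5.0, 5.52, "gray map A")
        assert t.percent_deviation == pytest.approx(10.4)
        assert t.verdict == "fail"


class TestCoefficientOfVariation:
    def test_constant_values(self):
        assert sq.coefficient_of_variation([5, 5, 5]) == 0.0

    def test_two_values_sample_sd(self):
        # sd([4,6]) = sqrt(2), mean 5 -> 28.284%
        assert sq.coefficient_of_variation([4, 6]) == pytest.approx(28.2842712, abs=1e-6)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sq.coefficient_of_variation([10])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            sq.coefficient_of_variation([-1, 1])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1.0, max_value=100.0), min_size=2, max_size=8),
        st.floats(min_value=0.1, max_value=50.0),
    )
    def test_scale_invariance(self, values, k):
        cv = sq.coefficient_of_variation(values)
        scaled = sq.coefficient_of_variation([k * v for v in values])
        assert scaled == pytest.approx(cv, rel=1e-9, abs=1e-9)


class TestRepeatability:
    def test_perfectly_reproducible_operators(self):
        res = sq.repeatability({"A": [10, 10], "B": [10, 10]})
        assert [cv for _, _, cv in res.per_operator] == [0.0, 0.0]
        assert res.inter_cv == 0.0

    def test_intra_and_inter_formulas(self):
        res = sq.repeatability({"A": [9, 11], "B": [10, 10]})
        assert res.per_operator[0][2] == pytest.approx(14.1421356, abs=1e-6)
        assert res.per_operator[1][2] == 0.0
        assert res.inter_cv == 0.0  # operator means are both 10

    def test_single_operator_warns_without_inter_cv(self):
        with pytest.warns(UserWarning, match="single operator"):
            res = sq.repeatability({"A": [9, 11]})
        assert res.inter_cv is None

    def test_pooled_alternative(self):
        res = sq.repeatability({"A": [9, 11], "B": [10, 10]}, inter_method="pooled")
        assert res.inter_cv == pytest.approx(
            sq.coefficient_of_variation([9, 11, 10, 10])
        )


class TestSensitivityLinearFit:
    def test_exact_256_over_dr_line(self):
        drs = [48.0, 69.0, 90.0]
        contrasts = [256.0 / d for d in drs]
        res = sq.sensitivity_linear_fit(drs, contrasts)
        assert res.verdict == "follows"
        assert res.fit[0] == pytest.approx(1.0)
        assert res.fit[2] == pytest.approx(1.0)

    def test_constant_contrast_is_flat(self):
        res = sq.sensitivity_linear_fit([48.0, 69.0, 90.0], [3.0, 3.0, 3.0])
        assert res.verdict == "flat"
        assert res.fit[0] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            sq.sensitivity_linear_fit([48.0, 48.0, 90.0], [5.0, 5.0, 3.0])

    def test_simulated_dr_series_follows(self):
        """Contrast slopes measured at several dynamic ranges follow 256/DR."""
        from dataclasses import replace

        cfg = sq.default_contrast_config()
        drs, slopes = [], []
        for dr in (48.0, 69.0, 90.0):
            c = replace(cfg, compression_slope=256.0 / dr)
            image, _ = sq.simulate_gel_image(c, seed=13)
            phantom = sq.phantom_model_for(c)
            lut = sq.GrayMapLUT.identity()
            rois = sq.locate_contrast_targets(image, phantom, lut=lut)
            slopes.append(sq.measure_contrast_response(image, rois, lut=lut).slope)
            drs.append(dr)
        res = sq.sensitivity_linear_fit(drs, slopes)
        assert res.verdict == "follows"
        assert res.fit[0] == pytest.approx(1.0, rel=0.10)


class TestTrendVerdict:
    def test_monotone_follow(self):
        assert sq.trend_verdict([100, 50, 20], [10.0, 9.1, 8.0], "decrease") == "follows"

    def test_small_change_is_flat(self):
        assert sq.trend_verdict([7, 8], [1.00, 1.01], "decrease") == "flat"

    def test_contradiction(self):
        assert sq.trend_verdict([100, 50], [10.0, 12.0], "decrease") == "contradicts"

    def test_unordered_parameters_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            sq.trend_verdict([1, 3, 2], [1, 2, 3], "increase")


class TestSuccessRate:
    def test_all_auto(self):
        assert sq.success_rate(["auto"] * 27).rate == 1.0

    def test_twelve_of_twentyseven(self):
        res = sq.success_rate(["auto"] * 12 + ["manual"] * 15)
        assert res.rate == pytest.approx(12 / 27)
        assert round(100 * res.rate, 1) == 44.4

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no outcomes"):
            sq.success_rate([])

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sq.success_rate(["auto", "semi"])


class TestBruteForceEquivalence:
    """The QA statistics must agree with direct textbook formulas."""

    def test_randomized_oracles(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            vals = rng.uniform(1.0, 100.0, size=rng.integers(2, 9))
            cv = sq.coefficient_of_variation(vals)
            n = vals.size
            mean = vals.sum() / n
            sd = np.sqrt(((vals - mean) ** 2).sum() / (n - 1))
            assert cv == pytest.approx(100 * sd / mean, rel=1e-9)

            m, b = rng.uniform(1, 100, size=2)
            assert sq.percent_deviation(m, b) == pytest.approx(100 * (m - b) / b, rel=1e-9)

    def test_linear_fit_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            drs = rng.uniform(40, 100, size=5)
            y = 256.0 / drs * rng.uniform(0.8, 1.2) + rng.normal(0, 0.05, 5)
            res = sq.sensitivity_linear_fit(drs, y)
            x = 256.0 / drs
            X = np.vstack([x, np.ones_like(x)]).T
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert res.fit[0] == pytest.approx(beta[0], rel=1e-9)
            assert res.fit[1] == pytest.approx(beta[1], rel=1e-9, abs=1e-9)
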