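"""Quantitative-core tests: integration, calibration, limits, CV, matrix."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glutenprm.quantify import (
    ChromatogramTrace,
    CalibrationCurve,
    back_calculate,
    cv,
    fit_calibration,
    integrate_xic,
    internal_standard_recovery,
    lod,
    lod_blank,
    lodloq_from_curve,
    loq,
    matrix_effect,
    replicability,
    residual_sd,
)
from glutenprm.simulate import DEFAULT_PEAK_MODELS, PeakModel, simulate_trace


def rectangle_trace(height=100.0, start=0.0, end=1.0, dt=0.01):
    t = np.arange(start, end + dt / 2, dt)
    return ChromatogramTrace("s", "x", t, np.full_like(t, height))


def normal_equations_fit(x, y):
    """Independent least-squares oracle via the normal equations."""
    design = np.column_stack([x, np.ones_like(x)])
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    return coef[0], coef[1]


class TestIntegrateXic:
    def test_rectangle(self):
        tr = rectangle_trace()
        assert integrate_xic(tr, (0.0, 1.0)) == pytest.approx(100.0)

    def test_all_zero(self):
        tr = rectangle_trace(height=0.0)
        assert integrate_xic(tr, (0.0, 1.0)) == 0.0

    def test_gaussian_matches_closed_form(self):
        m = PeakModel("X", rt_min=5.0, slope=3e6, intercept=5e4)
        tr = simulate_trace(m, 2.0, seed=0)
        got = integrate_xic(tr, (tr.time_min[0], tr.time_min[-1]))
        assert got == pytest.approx(m.slope * 2.0 + m.intercept, rel=0.005)

    def test_multiple_traces_summed(self):
        a = rectangle_trace(height=60.0)
        b = rectangle_trace(height=40.0)
        assert integrate_xic([a, b], (0.0, 1.0)) == pytest.approx(100.0)

    def test_linear_baseline_subtraction(self):
        t = np.linspace(0.0, 1.0, 101)
        ramp = 10.0 + 5.0 * t  # pure baseline, no peak
        tr = ChromatogramTrace("s", "x", t, ramp)
        assert integrate_xic(tr, (0.0, 1.0), baseline="linear") == 0.0

    def test_window_outside_span_rejected(self):
        tr = rectangle_trace()
        with pytest.raises(ValueError):
            integrate_xic(tr, (-1.0, 0.5))

    def test_empty_window_rejected(self):
        tr = rectangle_trace()
        with pytest.raises(ValueError):
            integrate_xic(tr, (0.5, 0.5))

    def test_floored_at_zero(self):
        t = np.linspace(0.0, 1.0, 11)
        tr = ChromatogramTrace("s", "x", t, np.full_like(t, -50.0))
        assert integrate_xic(tr, (0.0, 1.0)) == 0.0


class TestFitCalibration:
    def test_exact_line(self):
        curve = fit_calibration([1, 2, 3], [3, 5, 7])
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r == pytest.approx(1.0)
        assert curve.rss == pytest.approx(0.0, abs=1e-18)

    def test_symmetric_deviations(self):
        # replicated points +/- d around each level: line through means,
        # RSS = sum of d^2
        x = [1, 1, 2, 2, 3, 3]
        y = [2.9, 3.1, 4.9, 5.1, 6.9, 7.1]
        curve = fit_calibration(x, y)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.rss == pytest.approx(6 * 0.1**2)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([2, 2, 2], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([1, 2], [1, 2])

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.repeat([0.5, 1, 2, 5, 10], 2)
        y = 3e6 * x + 1e5 + rng.normal(0, 5e4, size=x.size)
        curve = fit_calibration(x, y)
        slope, intercept = normal_equations_fit(x, y)
        assert curve.slope == pytest.approx(slope, rel=1e-9)
        assert curve.intercept == pytest.approx(intercept, rel=1e-9)
        rss = float(((y - (slope * x + intercept)) ** 2).sum())
        assert curve.rss == pytest.approx(rss, rel=1e-9)

    def test_weighted_modes_exist(self):
        x = np.array([0.5, 1, 2, 5, 10])
        y = 2.0 * x + 0.5
        for w in ("1/x", "1/x2"):
            curve = fit_calibration(x, y, weighting=w)
            assert curve.slope == pytest.approx(2.0)


class TestDetectionLimits:
    def _curve(self, rss, n):
        return CalibrationCurve("p", slope=10.0, intercept=0.0, r=0.999,
                                rss=rss, n=n, conc_range=(0.5, 10.0))

    def test_residual_sd_examples(self):
        assert residual_sd(self._curve(0.0, 5)) == 0.0
        assert residual_sd(self._curve(8.0, 4)) == pytest.approx(2.0)

    def test_residual_sd_matches_direct_residuals(self):
        rng = np.random.default_rng(3)
        x = np.repeat([1.0, 2, 5, 10], 3)
        y = 4.0 * x + 2.0 + rng.normal(0, 0.5, x.size)
        curve = fit_calibration(x, y)
        slope, intercept = normal_equations_fit(x, y)
        resid = y - (slope * x + intercept)
        direct = math.sqrt((resid**2).sum() / (x.size - 2))
        assert residual_sd(curve) == pytest.approx(direct, rel=1e-9)

    def test_curve_with_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve("p", 1.0, 0.0, 1.0, 0.0, 2, (1, 3))

    def test_loq_lod_examples(self):
        assert loq(0.0, 10.0) == 0.0
        assert lod(0.0, 10.0) == 0.0
        assert loq(1.0, 10.0) == pytest.approx(1.0)
        assert lod(1.0, 10.0) == pytest.approx(0.33)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            loq(1.0, 0.0)
        with pytest.raises(ValueError):
            lod(1.0, 0.0)

    @given(st.floats(min_value=1e-6, max_value=1e9),
           st.floats(min_value=1e-6, max_value=1e9))
    def test_ratio_exactly_ten_over_three_point_three(self, s, slope):
        assert loq(s, slope) / lod(s, slope) == pytest.approx(
            10.0 / 3.3, rel=1e-12)

    def test_blank_rule(self):
        assert lod_blank([100, 100, 100], k=10) == pytest.approx(100.0)
        blanks = np.array([95.0, 100.0, 105.0])
        expected = blanks.mean() + 10 * blanks.std(ddof=1)
        assert lod_blank(blanks, k=10) == pytest.approx(expected)

    def test_blank_k_configurable(self):
        blanks = [95.0, 100.0, 105.0]
        hi = lod_blank(blanks, k=10)
        lo = lod_blank(blanks, k=3.3)
        assert (hi - 100.0) / (lo - 100.0) == pytest.approx(10 / 3.3)

    def test_blank_needs_two(self):
        with pytest.raises(ValueError):
            lod_blank([100.0])


class TestBackCalculate:
    def _curve(self):
        return CalibrationCurve("p", slope=1000.0, intercept=500.0,
                                r=1.0, rss=0.0, n=5, conc_range=(0.5, 10))

    def test_abundance_at_intercept(self):
        res = back_calculate(500.0, self._curve(), dilution_factor=1.0)
        assert res.raw_conc == 0.0

    def test_dilution_and_recovery(self):
        res = back_calculate(2500.0, self._curve(), dilution_factor=2.1,
                             is_recovery=0.8)
        assert res.raw_conc == pytest.approx(2.0)
        assert res.final_conc == pytest.approx(5.25)

    def test_conservation_invariant(self):
        res = back_calculate(3500.0, self._curve(), dilution_factor=1.7,
                             is_recovery=0.9)
        assert res.final_conc / res.raw_conc == pytest.approx(
            1.7 / 0.9, rel=1e-12)

    def test_negative_clipped_not_error(self):
        res = back_calculate(0.0, self._curve(), dilution_factor=1.0)
        assert res.raw_conc == 0.0
        assert res.clipped_negative

    def test_below_loq_flag(self):
        limits = lodloq_from_curve(
            CalibrationCurve("p", slope=1000.0, intercept=0.0, r=0.99,
                             rss=3e6, n=5, conc_range=(0.5, 10)))
        res = back_calculate(100.0, self._curve(), dilution_factor=1.0,
                             limits=limits)
        assert res.below_loq == (res.raw_conc < limits.loq)

    def test_bad_recovery_rejected(self):
        with pytest.raises(ValueError):
            back_calculate(1000.0, self._curve(), is_recovery=0.0)

    def test_simulated_round_trip_noise_free(self):
        m = DEFAULT_PEAK_MODELS["P1"]
        levels = [0.5, 1, 2, 5, 10]
        abundances = [
            integrate_xic(tr, (tr.time_min[0], tr.time_min[-1]))
            for tr in (simulate_trace(m, c, seed=0) for c in levels)
        ]
        curve = fit_calibration(levels, abundances, peptide="P1")
        unk = simulate_trace(m, 4.0, seed=1)
        ab = integrate_xic(unk, (unk.time_min[0], unk.time_min[-1]))
        res = back_calculate(ab, curve, dilution_factor=1.0)
        assert res.final_conc == pytest.approx(4.0, rel=1e-6)


class TestRecoveryAndMatrix:
    def test_recovery_examples(self):
        assert internal_standard_recovery(1000.0, 1000.0) == 1.0
        assert internal_standard_recovery(800.0, 1000.0) == 0.8

    def test_recovery_requires_positive_expected(self):
        with pytest.raises(ValueError):
            internal_standard_recovery(1.0, 0.0)

    def test_doubling_suppression_doubles_correction(self):
        curve = CalibrationCurve("p", 1000.0, 0.0, 1.0, 0.0, 5, (0.5, 10))
        mild = back_calculate(2000.0, curve, dilution_factor=1.0,
                              is_recovery=0.8)
        severe = back_calculate(2000.0, curve, dilution_factor=1.0,
                                is_recovery=0.4)
        assert severe.final_conc == pytest.approx(2 * mild.final_conc)

    def test_matrix_effect_examples(self):
        report = matrix_effect(1000.0, {0.75: 1000.0, 0.5: 800.0})
        assert report.percent_by_fraction[0.75] == 0.0
        assert report.percent_by_fraction[0.5] == pytest.approx(20.0)

    def test_enhancement_negative(self):
        report = matrix_effect(1000.0, {1.0: 1200.0})
        assert report.percent_by_fraction[1.0] == pytest.approx(-20.0)

    def test_control_must_be_positive(self):
        with pytest.raises(ValueError):
            matrix_effect(0.0, {1.0: 1.0})

    def test_simulated_suppression_recovered(self):
        from glutenprm.simulate import matrix_series
        ss = matrix_series(DEFAULT_PEAK_MODELS["P1H"],
                           suppression={1.0: 0.7, 0.5: 0.9}, seed=11)
        areas = {
            t.sample_id: integrate_xic(
                t, (t.time_min[0], t.time_min[-1]))
            for t in ss.traces
        }
        report = matrix_effect(areas["control"], {
            1.0: areas["matrix_1"], 0.5: areas["matrix_0.5"]})
        assert report.percent_by_fraction[1.0] == pytest.approx(30.0,
                                                                abs=0.1)
        assert report.percent_by_fraction[0.5] == pytest.approx(10.0,
                                                                abs=0.1)


class TestCv:
    def test_constant_values(self):
        assert cv([5, 5, 5]) == 0.0

    def test_example(self):
        assert cv([8, 10, 12]) == pytest.approx(20.0)

    def test_scale_invariance(self):
        values = [3.0, 4.0, 5.5]
        assert cv([7 * v for v in values]) == pytest.approx(cv(values))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv([-1.0, 1.0])

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            cv([1.0])

    def test_generator_cv_recovered_over_many_repeats(self):
        # day series drawn with 5% generator CV: per-repeat CVs centre
        # near 5%, and the mean over 1000 seeded repeats lands in [3, 7]
        rng = np.random.default_rng(2024)
        cvs = []
        for _ in range(1000):
            day_means = 10.0 * rng.normal(1.0, 0.05, size=3)
            cvs.append(cv(day_means))
        mean_cv = float(np.mean(cvs))
        assert 3.0 < mean_cv < 7.0
        assert abs(mean_cv - 5.0) < 1.0


class TestReplicability:
    def test_report(self):
        report = replicability(
            {0: [10.1, 10.3], 1: [10.6, 10.4], 2: [9.8, 10.0]},
            peptide="P1")
        assert report.passes
        assert report.grand_mean == pytest.approx(10.2, abs=0.01)

    def test_fail_flag(self):
        report = replicability({0: [1.0], 1: [3.0], 2: [5.0]})
        assert not report.passes

    def test_needs_two_days(self):
        with pytest.raises(ValueError):
            replicability({0: [1.0, 2.0]})
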