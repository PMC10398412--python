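import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import progrisk as pr
from progrisk.risk import OUT_OF_RANGE, ZERO_DENOMINATOR, ZERO_NUMERATOR


def series_from_values(S):
    S = np.asarray(S, dtype=float)
    return pr.DailySurvivalSeries(day=np.arange(len(S)), S=S)


def risk_curve(values, window=30, mode=pr.ABSOLUTE):
    values = np.asarray(values, dtype=float)
    return pr.RiskCurve(day=np.arange(len(values)), value=values,
                        window_days=window, mode=mode)


def rr_curve(values):
    values = np.asarray(values, dtype=float)
    reason = np.where(np.isnan(values), OUT_OF_RANGE, "").astype(object)
    return pr.RelativeRiskCurve(day=np.arange(len(values)), value=values,
                                reason=reason, window_days=30, mode=pr.ABSOLUTE)


class TestProgressionRisk:
    def test_hand_arithmetic_both_modes(self):
        S = np.concatenate([[1.0] * 30, np.full(31, 0.9)])
        series = series_from_values(np.minimum.accumulate(S))
        absolute = pr.progression_risk(series, 30, pr.ABSOLUTE)
        conditional = pr.progression_risk(series, 30, pr.CONDITIONAL)
        assert absolute.value[0] == pytest.approx(0.1)
        assert conditional.value[0] == pytest.approx(0.1)

    def test_flat_series_has_zero_risk(self):
        curve = pr.progression_risk(series_from_values(np.ones(100)), 30)
        assert np.all(curve.value[~curve.missing] == 0.0)

    def test_exponential_closed_form(self, exponential_series):
        absolute = pr.progression_risk(exponential_series, 30, pr.ABSOLUTE)
        conditional = pr.progression_risk(exponential_series, 30, pr.CONDITIONAL)
        days = np.arange(0, 471)
        expected_abs = np.exp(-0.01 * days) * (1 - np.exp(-0.3))
        assert np.allclose(absolute.value[:471], expected_abs, atol=1e-12)
        assert np.allclose(conditional.value[:471], 1 - np.exp(-0.3), atol=1e-12)

    def test_tail_beyond_horizon_is_missing(self, exponential_series):
        curve = pr.progression_risk(exponential_series, 30)
        assert np.all(curve.missing[-30:])
        assert not np.any(curve.missing[:-30])

    def test_invalid_window_rejected(self, exponential_series):
        with pytest.raises(ValueError):
            pr.progression_risk(exponential_series, 0)


class TestRelativeRisk:
    def test_ratio_and_incalculability_reasons(self):
        treat = risk_curve([0.05, 0.05, 0.0, np.nan])
        ctrl = risk_curve([0.10, 0.0, 0.1, 0.1])
        rr = pr.relative_risk(treat, ctrl)
        assert rr.value[0] == pytest.approx(0.5)
        assert np.isnan(rr.value[1]) and rr.reason[1] == ZERO_DENOMINATOR
        assert np.isnan(rr.value[2]) and rr.reason[2] == ZERO_NUMERATOR
        assert np.isnan(rr.value[3]) and rr.reason[3] == OUT_OF_RANGE

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pr.relative_risk(risk_curve([0.1, 0.1]), risk_curve([0.1, 0.1, 0.1]))

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pr.relative_risk(
                risk_curve([0.1], mode=pr.ABSOLUTE), risk_curve([0.1], mode=pr.CONDITIONAL)
            )


class TestSmooth:
    def test_constant_series_unchanged(self):
        curve = risk_curve(np.full(300, 0.25))
        assert np.allclose(pr.smooth(curve, 60).value, 0.25)

    def test_unit_impulse_spreads_to_plateau(self):
        values = np.zeros(400)
        values[200] = 1.0
        smoothed = pr.smooth(risk_curve(values), 60)
        inside = np.arange(140, 261)
        assert np.allclose(smoothed.value[inside], 1 / 121)
        assert np.allclose(smoothed.value[:139], 0.0)

    def test_zero_halfwidth_is_identity(self):
        values = np.random.default_rng(0).random(50)
        assert np.array_equal(pr.smooth(risk_curve(values), 0).value, values)

    def test_missing_values_excluded_not_propagated(self):
        values = np.full(200, 0.5)
        values[100] = np.nan
        smoothed = pr.smooth(risk_curve(values), 60)
        assert np.allclose(smoothed.value, 0.5)

    def test_all_missing_window_stays_missing(self):
        values = np.full(50, np.nan)
        assert np.all(np.isnan(pr.smooth(risk_curve(values), 10).value))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(0, 40))
    def test_smoothing_stays_within_input_range(self, seed, halfwidth):
        rng = np.random.default_rng(seed)
        values = rng.random(rng.integers(2, 200))
        smoothed = pr.smooth(risk_curve(values), halfwidth).value
        assert np.nanmin(smoothed) >= values.min() - 1e-12
        assert np.nanmax(smoothed) <= values.max() + 1e-12


class TestDetectRebound:
    def test_risk_reduction_throughout_means_no_rebound(self):
        report = pr.detect_rebound(rr_curve(np.full(800, 0.8)), 365)
        assert not report.rebound_detected and report.onset_day is None

    def test_step_crossing_at_discontinuation_detected(self):
        values = np.where(np.arange(800) < 365, 0.7, 1.3)
        report = pr.detect_rebound(rr_curve(values), 365)
        assert report.rebound_detected and report.onset_day == 365
        assert report.pre_min_rr == pytest.approx(0.7)
        assert report.peak_rr == pytest.approx(1.3)

    def test_short_excursion_below_run_length_ignored(self):
        values = np.full(800, 0.9)
        values[400:420] = 1.5  # 20 days < 30-day run requirement
        report = pr.detect_rebound(rr_curve(values), 365, run_days=30)
        assert not report.rebound_detected

    def test_missing_post_segment_is_indeterminate(self):
        values = np.concatenate([np.full(365, 0.8), np.full(100, np.nan)])
        report = pr.detect_rebound(rr_curve(values), 365)
        assert report.indeterminate

    def test_discontinuation_off_grid_rejected(self):
        with pytest.raises(ValueError):
            pr.detect_rebound(rr_curve(np.ones(100)), 500)

    def test_simulated_rebound_scenario_detected_in_window(
        self, icon7_scenario, icon7_series
    ):
        risk = {
            a: pr.progression_risk(icon7_series[a], 30, pr.CONDITIONAL) for a in (0, 1)
        }
        rr = pr.smooth(pr.relative_risk(risk[1], risk[0]), 60)
        report = pr.detect_rebound(rr, 365, run_days=30)
        assert report.rebound_detected
        assert 365 <= report.onset_day <= 450
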