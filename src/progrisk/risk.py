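"""Windowed progression-risk curves, relative risk, smoothing, and rebound.

The central statistic: the progression risk at day t is the decrease of the
survival curve over the following 30 days, risk(t) = S(t) - S(t+30)
(optionally divided by S(t) to condition on being progression-free at t).
The treated/control ratio of these risks is the relative-risk curve; days
where either arm's risk is zero are incalculable and carried as missing
with a reason code.  Both curves are smoothed by a simple moving average
over the 60 days before and after each day, and a sustained excursion of
the smoothed relative risk above 1 after the scheduled treatment stop is
reported as a rebound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .series import DailySurvivalSeries

ABSOLUTE = "absolute"
CONDITIONAL = "conditional"

# missingness reason codes on relative-risk curves
ZERO_DENOMINATOR = "zero-denominator"
ZERO_NUMERATOR = "zero-numerator-rule"
OUT_OF_RANGE = "out-of-range"


@dataclass
class RiskCurve:
    """Windowed progression risk per day; NaN where not computable."""

    day: np.ndarray
    value: np.ndarray
    window_days: int
    mode: str
    label: str = ""

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "risk": self.value, "missing": self.missing}
        )


@dataclass
class RelativeRiskCurve:
    """Treated/control risk ratio per day with reason-coded missingness."""

    day: np.ndarray
    value: np.ndarray
    reason: np.ndarray  # "" where defined
    window_days: int
    mode: str
    label: str = ""

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "rr": self.value,
                "missing": self.missing,
                "reason": self.reason,
            }
        )


@dataclass
class ReboundReport:
    """Post-discontinuation excess-risk summary from a smoothed RR curve."""

    discontinuation_day: int
    rebound_detected: bool
    indeterminate: bool
    onset_day: int | None
    peak_rr: float | None
    peak_day: int | None
    pre_min_rr: float | None
    pre_min_day: int | None
    run_days: int

    def to_dict(self) -> dict:
        return {
            "discontinuation_day": self.discontinuation_day,
            "rebound_detected": self.rebound_detected,
            "indeterminate": self.indeterminate,
            "onset_day": self.onset_day,
            "peak_rr": self.peak_rr,
            "peak_day": self.peak_day,
            "pre_min_rr": self.pre_min_rr,
            "pre_min_day": self.pre_min_day,
            "run_days": self.run_days,
        }


def progression_risk(
    series: DailySurvivalSeries, window_days: int = 30, mode: str = ABSOLUTE
) -> RiskCurve:
    """Risk(t) = S(t) - S(t+window); conditional mode divides by S(t).

    Days with t+window beyond the series horizon are missing; conditional
    risk is additionally missing where S(t) = 0 (nobody left at risk).
    """
    if window_days <= 0:
        raise ValueError("window_days must be > 0")
    if mode not in (ABSOLUTE, CONDITIONAL):
        raise ValueError(f"unknown mode {mode!r}")
    if not series.is_daily():
        raise ValueError("risk curves need survival on every integer day 0..horizon")
    if series.horizon < window_days:
        raise ValueError("series horizon shorter than the risk window")
    S = series.S
    n = len(S)
    value = np.full(n, np.nan)
    value[: n - window_days] = S[: n - window_days] - S[window_days:]
    if mode == CONDITIONAL:
        with np.errstate(divide="ignore", invalid="ignore"):
            value = np.where(S > 0, value / S, np.nan)
    return RiskCurve(
        day=series.day.copy(), value=value, window_days=window_days, mode=mode,
        label=series.label,
    )


def relative_risk(risk_treat: RiskCurve, risk_ctrl: RiskCurve) -> RelativeRiskCurve:
    """RR(t) = risk_treat(t) / risk_ctrl(t), with the incalculability rule.

    The ratio is missing wherever either arm's risk is zero (reason codes
    ``zero-denominator`` / ``zero-numerator-rule``) or either input is
    itself missing (``out-of-range``).
    """
    if len(risk_treat.day) != len(risk_ctrl.day) or np.any(risk_treat.day != risk_ctrl.day):
        raise ValueError("risk curves must share the same day grid")
    if risk_treat.window_days != risk_ctrl.window_days or risk_treat.mode != risk_ctrl.mode:
        raise ValueError("risk curves must share window and mode")
    rt, rc = risk_treat.value, risk_ctrl.value
    n = len(rt)
    value = np.full(n, np.nan)
    reason = np.full(n, "", dtype=object)

    input_missing = np.isnan(rt) | np.isnan(rc)
    zero_den = ~input_missing & (rc == 0)
    zero_num = ~input_missing & ~zero_den & (rt == 0)
    ok = ~input_missing & ~zero_den & ~zero_num
    value[ok] = rt[ok] / rc[ok]
    reason[input_missing] = OUT_OF_RANGE
    reason[zero_den] = ZERO_DENOMINATOR
    reason[zero_num] = ZERO_NUMERATOR
    return RelativeRiskCurve(
        day=risk_treat.day.copy(), value=value, reason=reason,
        window_days=risk_treat.window_days, mode=risk_treat.mode,
    )


def _moving_mean(value: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving average ignoring NaNs; NaN where the window is empty."""
    if halfwidth == 0:
        return value.copy()
    n = len(value)
    obs = ~np.isnan(value)
    vals = np.where(obs, value, 0.0)
    cum_v = np.concatenate([[0.0], np.cumsum(vals)])
    cum_n = np.concatenate([[0], np.cumsum(obs)])
    lo = np.maximum(np.arange(n) - halfwidth, 0)
    hi = np.minimum(np.arange(n) + halfwidth, n - 1) + 1
    counts = cum_n[hi] - cum_n[lo]
    sums = cum_v[hi] - cum_v[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def smooth(curve, halfwidth_days: int = 60):
    """Simple moving average over the ``halfwidth_days`` before and after t.

    Missing values are excluded from each window's mean (so isolated
    incalculable days do not erase the curve); the window is truncated at
    the grid edges.  Returns a curve of the same type; on a
    :class:`RelativeRiskCurve` the surviving missing days are recoded
    ``out-of-range`` (no data in the whole window).
    """
    if halfwidth_days < 0:
        raise ValueError("halfwidth_days must be >= 0")
    sm_value = _moving_mean(curve.value, halfwidth_days)
    if isinstance(curve, RelativeRiskCurve):
        reason = np.where(np.isnan(sm_value), OUT_OF_RANGE, "").astype(object)
        return replace(curve, value=sm_value, reason=reason)
    return replace(curve, value=sm_value)


def detect_rebound(
    rr: RelativeRiskCurve, discontinuation_day: int, run_days: int = 30
) -> ReboundReport:
    """Find a sustained post-discontinuation excess risk on a smoothed curve.

    A rebound is the first day >= ``discontinuation_day`` at which the
    smoothed relative risk exceeds 1 on at least ``run_days`` consecutive
    non-missing grid days.  Also reports the pre-discontinuation minimum and
    the post-discontinuation peak.  If every post-discontinuation day is
    missing the report is flagged indeterminate.
    """
    day = rr.day
    if discontinuation_day < day[0] or discontinuation_day > day[-1]:
        raise ValueError("discontinuation_day must lie on the analyzed grid")
    value = rr.value
    post = day >= discontinuation_day
    pre = day < discontinuation_day

    post_vals = value[post]
    post_days = day[post]
    indeterminate = bool(np.all(np.isnan(post_vals)))

    onset = None
    if not indeterminate:
        above = ~np.isnan(post_vals) & (post_vals > 1.0)
        run = 0
        for i, flag in enumerate(above):
            run = run + 1 if flag else 0
            if run >= run_days:
                onset = int(post_days[i - run_days + 1])
                break

    def _extreme(mask, fn):
        v = value[mask]
        d = day[mask]
        keep = ~np.isnan(v)
        if not keep.any():
            return None, None
        v, d = v[keep], d[keep]
        i = fn(v)
        return float(v[i]), int(d[i])

    peak_rr, peak_day = _extreme(post, np.argmax)
    pre_min_rr, pre_min_day = _extreme(pre, np.argmin)

    return ReboundReport(
        discontinuation_day=int(discontinuation_day),
        rebound_detected=onset is not None,
        indeterminate=indeterminate,
        onset_day=onset,
        peak_rr=peak_rr,
        peak_day=peak_day,
        pre_min_rr=pre_min_rr,
        pre_min_day=pre_min_day,
        run_days=run_days,
    )
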