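"""Product-limit estimation, log-rank testing, and a hazard-ratio
constancy diagnostic.

The Kaplan-Meier estimator here supports case weights (needed by the
inverse-probability-weighted analyses) and uses the standard tie rule:
events precede censorings at equal times, i.e. subjects censored at t are
still at risk for events at t.  The step function is right-continuous and
all consumers evaluate it through :meth:`StepSurvivalFunction.survival_at`
rather than indexing raw arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank

from .series import DailySurvivalSeries, EXTRAPOLATED, OBSERVED


@dataclass
class StepSurvivalFunction:
    """Right-continuous Kaplan-Meier step function with Greenwood variance.

    ``survival_after[i]`` is S(t) just after ``event_times[i]``; before the
    first event time S = 1.  ``max_time`` is the largest observed follow-up
    (event or censoring), beyond which lookups are extrapolations.
    """

    event_times: np.ndarray
    survival_after: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    greenwood_var: np.ndarray
    n_total: float
    max_time: float
    label: str = ""

    def survival_at(self, day: float, with_flag: bool = False):
        """S(day) by right-continuous step lookup.

        Days beyond the last observed time return the last value; with
        ``with_flag=True`` the second element reports that extrapolation.
        """
        scalar = np.isscalar(day)
        d = np.atleast_1d(np.asarray(day, dtype=float))
        if np.any(d < 0):
            raise ValueError("day must be >= 0")
        idx = np.searchsorted(self.event_times, d, side="right") - 1
        if len(self.survival_after):
            S = np.where(idx >= 0, self.survival_after[np.maximum(idx, 0)], 1.0)
        else:
            S = np.ones_like(d)
        flag = d > self.max_time
        if scalar:
            S, flag = float(S[0]), bool(flag[0])
        if with_flag:
            return S, flag
        return S

    def variance_at(self, day: float):
        """Greenwood variance of S at ``day`` (0 before the first event)."""
        d = np.atleast_1d(np.asarray(day, dtype=float))
        idx = np.searchsorted(self.event_times, d, side="right") - 1
        v = np.where(idx >= 0, self.greenwood_var[np.maximum(idx, 0)], 0.0)
        return float(v[0]) if np.isscalar(day) else v

    def to_daily_series(self, horizon: int, label: str | None = None) -> DailySurvivalSeries:
        days = np.arange(horizon + 1)
        S, flags = self.survival_at(days.astype(float), with_flag=True)
        prov = np.where(flags, EXTRAPOLATED, OBSERVED).astype(object)
        return DailySurvivalSeries(day=days, S=S, provenance=prov,
                                   label=label if label is not None else self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.event_times,
                "S": self.survival_after,
                "var": self.greenwood_var,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


def km_estimate(
    records: pd.DataFrame,
    arm_filter: int | None = None,
    weights: np.ndarray | None = None,
    label: str = "",
) -> StepSurvivalFunction:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``records`` is the ``time,event[,arm]`` table; ``arm_filter`` restricts
    to one arm.  Optional per-record ``weights`` give the weighted estimator
    used by the IPW-adjusted analysis (Greenwood variance is then only a
    working quantity; inference should bootstrap).
    """
    df = records
    if arm_filter is not None:
        df = df[df["arm"] == arm_filter]
    if len(df) == 0:
        raise ValueError("no records to estimate from")
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    if weights is None:
        w = np.ones(len(df))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(records):
            raise ValueError("weights must align with records")
        if arm_filter is not None:
            w = w[(records["arm"] == arm_filter).to_numpy()]
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")

    order = np.argsort(time, kind="stable")
    time, event, w = time[order], event[order], w[order]
    n_total = float(w.sum())

    uniq = np.unique(time[event == 1])
    # events-first tie rule: at-risk mass at t counts everyone with time >= t
    cum_w = np.concatenate([[0.0], np.cumsum(w)])
    at_risk = n_total - cum_w[np.searchsorted(time, uniq, side="left")]
    d = np.array([w[(time == t) & (event == 1)].sum() for t in uniq])

    frac = 1.0 - d / at_risk
    S = np.cumprod(frac)
    # when d == n the estimate hits 0 (degenerate; variance set to 0 there)
    gw_terms = np.where(at_risk > d, d / (at_risk * np.maximum(at_risk - d, 1e-300)), 0.0)
    gw = S**2 * np.cumsum(gw_terms)

    return StepSurvivalFunction(
        event_times=uniq,
        survival_after=S,
        n_risk=at_risk,
        n_event=d,
        greenwood_var=gw,
        n_total=n_total,
        max_time=float(time.max()),
        label=label,
    )


def logrank(records: pd.DataFrame) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and p-value, arms 0 vs 1."""
    arms = set(records["arm"].unique())
    if arms != {0, 1}:
        raise ValueError("log-rank needs exactly arms 0 and 1")
    if records["event"].sum() < 1:
        raise ValueError("log-rank needs at least one event")
    g0 = records[records["arm"] == 0]
    g1 = records[records["arm"] == 1]
    res = _ll_logrank(
        g0["time"], g1["time"], event_observed_A=g0["event"], event_observed_B=g1["event"]
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class PhDiagnostic:
    """Piecewise person-time hazard-ratio homogeneity diagnostic.

    A period-by-period hazard ratio from events and person-time in each arm,
    with a likelihood-ratio test of a common ratio against one ratio per
    period under a Poisson person-time model.  A small p-value indicates a
    time-varying treatment effect (proportional-hazards violation).
    """

    cut_days: tuple[float, ...]
    table: pd.DataFrame  # period, start, end, d0, T0, d1, T1, hr, excluded
    statistic: float
    df: int
    p_value: float
    excluded_periods: tuple[int, ...] = field(default_factory=tuple)


def ph_constancy_test(
    records: pd.DataFrame, cut_days: list[float], horizon: float | None = None
) -> PhDiagnostic:
    """Test constancy of the between-arm hazard ratio across time periods.

    Periods partition [0, horizon) at ``cut_days``.  Within period k the
    hazard ratio is (d1k/T1k)/(d0k/T0k); the homogeneity statistic is the
    likelihood-ratio between Poisson models with one ratio per period and a
    common ratio, on chi-square with (#periods - 1) df.  Periods with zero
    person-time in either arm are flagged and excluded (df reduced).
    """
    import statsmodels.api as sm

    cut_days = list(cut_days)
    if any(b <= a for a, b in zip(cut_days, cut_days[1:])):
        raise ValueError("cut_days must be strictly ascending")
    tmax = float(records["time"].max())
    if horizon is None:
        horizon = tmax
    if any(c <= 0 or c >= horizon for c in cut_days):
        raise ValueError("cut_days must lie inside (0, horizon)")

    edges = [0.0] + cut_days + [horizon]
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    arm = records["arm"].to_numpy(dtype=int)

    rows = []
    for k, (a, b) in enumerate(zip(edges, edges[1:])):
        for g in (0, 1):
            m = arm == g
            expo = np.clip(np.minimum(time[m], b) - a, 0.0, None).sum()
            dk = int(((time[m] > a) & (time[m] <= b) & (event[m] == 1)).sum())
            rows.append({"period": k, "start": a, "end": b, "arm": g,
                         "events": dk, "person_time": expo})
    long = pd.DataFrame(rows)

    wide = long.pivot(index="period", columns="arm", values=["events", "person_time"])
    excluded = tuple(
        int(k) for k in wide.index
        if wide.loc[k, ("person_time", 0)] <= 0 or wide.loc[k, ("person_time", 1)] <= 0
    )
    kept = [k for k in wide.index if k not in excluded]
    if len(kept) < 2:
        raise ValueError("need at least two usable periods to test constancy")

    sub = long[long["period"].isin(kept)].copy()
    period_dummies = pd.get_dummies(sub["period"], prefix="p", dtype=float)
    offset = np.log(sub["person_time"].to_numpy())

    x_null = pd.concat([period_dummies, sub["arm"].astype(float)], axis=1)
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        # zero-event cells on degenerate inputs trigger a spurious warning
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        null_fit = sm.GLM(sub["events"].to_numpy(), x_null.to_numpy(), offset=offset,
                          family=sm.families.Poisson()).fit()
    # full model is saturated in (period x arm) cells: closed-form loglik
    d = sub["events"].to_numpy(dtype=float)
    # loglik on the count scale (log d! terms cancel in the ratio)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_full = float(np.sum(np.where(d > 0, d * np.log(np.where(d > 0, d, 1.0)), 0.0) - d))
    mu_null = null_fit.mu
    ll_null = float(np.sum(np.where(d > 0, d * np.log(mu_null), 0.0) - mu_null))

    stat = max(0.0, 2.0 * (ll_full - ll_null))
    dof = len(kept) - 1
    from scipy.stats import chi2

    p = float(chi2.sf(stat, dof))

    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (wide[("events", 1)] / wide[("person_time", 1)]) / (
            wide[("events", 0)] / wide[("person_time", 0)]
        )
    table = pd.DataFrame(
        {
            "period": wide.index,
            "start": edges[:-1],
            "end": edges[1:],
            "d0": wide[("events", 0)],
            "T0": wide[("person_time", 0)],
            "d1": wide[("events", 1)],
            "T1": wide[("person_time", 1)],
            "hr": hr,
            "excluded": [k in excluded for k in wide.index],
        }
    ).reset_index(drop=True)
    return PhDiagnostic(
        cut_days=tuple(cut_days), table=table, statistic=stat, df=dof,
        p_value=p, excluded_periods=excluded,
    )
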