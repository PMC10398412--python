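"""Restricted mean survival time: estimation, arm comparison, landmark
splits, and inverse-probability-weighted adjustment.

RMST up to a horizon tau is the area under the survival curve on [0, tau]
— the mean event-free time over that window — and remains interpretable
when the proportional-hazards assumption fails.  Comparisons report the
between-arm difference (normal-approximation CI) and ratio (delta-method
CI on the log scale).  "Before/after discontinuation" contrasts use a
landmark construction: the pre period censors everyone at the landmark,
the post period re-zeroes follow-up among subjects still at risk there.
Covariate adjustment reweights each subject by the inverse of their
estimated treatment-assignment probability (stabilized), and the weighted
comparison is bootstrapped for inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .km import StepSurvivalFunction, km_estimate

UNADJUSTED = "unadjusted"
IPW = "IPW"


@dataclass
class RmstResult:
    """Two-arm RMST comparison at horizon ``tau``."""

    tau: float
    rmst_by_arm: dict  # arm -> estimate
    se_by_arm: dict  # arm -> SE (NaN when only bootstrap inference is available)
    difference: float  # treated - control
    difference_ci: tuple[float, float]
    difference_p: float
    ratio: float  # treated / control
    ratio_ci: tuple[float, float]
    ratio_p: float
    landmark_day: float | None = None
    weighting: str = UNADJUSTED
    n_by_arm: dict = field(default_factory=dict)

    def __post_init__(self):
        for a, m in self.rmst_by_arm.items():
            if not (0 < m <= self.tau + 1e-9):
                raise ValueError(f"arm {a}: RMST {m} outside (0, tau]")
        if self.difference_ci[0] > self.difference_ci[1] or self.ratio_ci[0] > self.ratio_ci[1]:
            raise ValueError("CI bounds out of order")
        if self.ratio <= 0:
            raise ValueError("RMST ratio must be > 0")

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "landmark_day": self.landmark_day,
            "weighting": self.weighting,
            "rmst_control": self.rmst_by_arm[0],
            "rmst_treated": self.rmst_by_arm[1],
            "se_control": self.se_by_arm[0],
            "se_treated": self.se_by_arm[1],
            "difference": self.difference,
            "difference_ci_low": self.difference_ci[0],
            "difference_ci_high": self.difference_ci[1],
            "difference_p": self.difference_p,
            "ratio": self.ratio,
            "ratio_ci_low": self.ratio_ci[0],
            "ratio_ci_high": self.ratio_ci[1],
            "ratio_p": self.ratio_p,
        }


def rmst(sf: StepSurvivalFunction, tau: float) -> tuple[float, float]:
    """Exact step-function area on [0, tau] and its Greenwood-based SE.

    The variance integrates the squared remaining area against the
    Greenwood increments: var = sum_i A_i^2 d_i / (n_i (n_i - d_i)) with
    A_i the area under S from t_i to tau (the standard formula behind
    restricted-mean software).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if tau > sf.max_time + 1e-9:
        raise ValueError(
            f"tau={tau} exceeds the last observed time {sf.max_time}; lower tau"
        )
    t = sf.event_times
    S = sf.survival_after
    inside = t < tau
    t_in, S_in = t[inside], S[inside]
    knots = np.concatenate([[0.0], t_in, [tau]])
    heights = np.concatenate([[1.0], S_in])
    widths = np.diff(knots)
    area = float(np.sum(heights * widths))

    # remaining area past each event time (for the variance integrand)
    seg_area = heights * widths
    rev_cum = np.cumsum(seg_area[::-1])[::-1]
    # area from t_i to tau = sum of segments starting at t_i
    A = rev_cum[1:] if len(t_in) else np.array([])
    n_i = sf.n_risk[inside]
    d_i = sf.n_event[inside]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_i > d_i, d_i / (n_i * (n_i - d_i)), 0.0)
    var = float(np.sum(A**2 * terms))
    return area, float(np.sqrt(var))


def default_tau(records: pd.DataFrame) -> float:
    """Smaller of the two arms' largest observed times (survRM2 convention)."""
    return float(records.groupby("arm")["time"].max().min())


def rmst_compare(
    records: pd.DataFrame,
    tau: float | None = None,
    landmark_day: float | None = None,
    alpha: float = 0.05,
) -> RmstResult:
    """Compare arm 1 vs arm 0 RMST at horizon ``tau``.

    Difference CI by normal approximation on the two SEs; ratio CI by the
    delta method on the log scale; two-sided p-values.
    """
    arms = set(records["arm"].unique())
    if arms != {0, 1}:
        raise ValueError("need exactly arms 0 and 1")
    if tau is None:
        tau = default_tau(records)
    est, se, n = {}, {}, {}
    for a in (0, 1):
        sub = records[records["arm"] == a]
        if sub["event"].sum() == 0 and sub["time"].max() <= 0:
            raise ValueError(f"arm {a} has no usable follow-up")
        est[a], se[a] = rmst(km_estimate(sub), tau)
        n[a] = len(sub)

    z = norm.ppf(1 - alpha / 2)
    diff = est[1] - est[0]
    se_diff = float(np.hypot(se[0], se[1]))
    diff_ci = (diff - z * se_diff, diff + z * se_diff)
    diff_p = 2 * norm.sf(abs(diff) / se_diff) if se_diff > 0 else 1.0

    ratio = est[1] / est[0]
    se_log = float(np.sqrt((se[1] / est[1]) ** 2 + (se[0] / est[0]) ** 2))
    ratio_ci = (ratio * np.exp(-z * se_log), ratio * np.exp(z * se_log))
    ratio_p = 2 * norm.sf(abs(np.log(ratio)) / se_log) if se_log > 0 else 1.0

    return RmstResult(
        tau=tau, rmst_by_arm=est, se_by_arm=se,
        difference=diff, difference_ci=diff_ci, difference_p=float(diff_p),
        ratio=ratio, ratio_ci=ratio_ci, ratio_p=float(ratio_p),
        landmark_day=landmark_day, weighting=UNADJUSTED, n_by_arm=n,
    )


def landmark_split(
    records: pd.DataFrame, landmark_day: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split follow-up at a landmark (the scheduled discontinuation day).

    Pre: every subject, follow-up capped at the landmark, events after it
    recoded as censored there.  Post: only subjects still at risk (no event
    and not censored) at the landmark, with time re-zeroed.  Rejects a
    landmark leaving fewer than two at-risk subjects in either arm.
    """
    if landmark_day < 0 or landmark_day >= records["time"].max():
        raise ValueError("landmark must lie within follow-up")
    pre = records.copy()
    after = pre["time"] > landmark_day
    if landmark_day > 0:
        pre.loc[after, "event"] = 0
        pre.loc[after, "time"] = landmark_day

    post = records[records["time"] > landmark_day].copy()
    post["time"] = post["time"] - landmark_day
    counts = post.groupby("arm").size()
    for a in records["arm"].unique():
        if landmark_day > 0 and counts.get(a, 0) < 2:
            raise ValueError(
                f"landmark leaves fewer than 2 at-risk subjects in arm {a}"
            )
    return pre, post


def interval_rmst_compare(
    records: pd.DataFrame, start_day: float, tau: float, alpha: float = 0.05
) -> RmstResult:
    """RMST contrast on [start_day, tau] without landmark conditioning.

    Integrates each arm's unconditional survival curve over the interval
    (difference of RMST(tau) and RMST(start)); the alternative reading of a
    "after discontinuation" contrast, provided alongside the landmark one.
    """
    if not 0 <= start_day < tau:
        raise ValueError("need 0 <= start_day < tau")
    est, se, n = {}, {}, {}
    z = norm.ppf(1 - alpha / 2)
    for a in (0, 1):
        sf = km_estimate(records[records["arm"] == a])
        m_tau, s_tau = rmst(sf, tau)
        m_start, s_start = (0.0, 0.0) if start_day == 0 else rmst(sf, start_day)
        est[a] = m_tau - m_start
        # conservative: SEs of nested areas are strongly correlated
        se[a] = float(np.sqrt(max(s_tau**2 - s_start**2, 0.0)))
        n[a] = int((records["arm"] == a).sum())
    diff = est[1] - est[0]
    se_diff = float(np.hypot(se[0], se[1]))
    ratio = est[1] / est[0]
    se_log = float(np.sqrt((se[1] / est[1]) ** 2 + (se[0] / est[0]) ** 2))
    return RmstResult(
        tau=tau - start_day,
        rmst_by_arm=est, se_by_arm=se,
        difference=diff,
        difference_ci=(diff - z * se_diff, diff + z * se_diff),
        difference_p=float(2 * norm.sf(abs(diff) / se_diff)) if se_diff > 0 else 1.0,
        ratio=ratio,
        ratio_ci=(ratio * np.exp(-z * se_log), ratio * np.exp(z * se_log)),
        ratio_p=float(2 * norm.sf(abs(np.log(ratio)) / se_log)) if se_log > 0 else 1.0,
        landmark_day=start_day, weighting=UNADJUSTED, n_by_arm=n,
    )


# ---------------------------------------------------------------------------
# inverse probability weighting
# ---------------------------------------------------------------------------

@dataclass
class IpwModel:
    """Fitted treatment-assignment model and stabilized weights."""

    covariates: list[str]
    coefficients: pd.Series
    propensity: np.ndarray
    weights: np.ndarray
    diagnostics: dict

    def __post_init__(self):
        if np.any((self.propensity <= 0) | (self.propensity >= 1)):
            raise ValueError("fitted probabilities must lie in (0, 1)")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be > 0")


def fit_ipw(records: pd.DataFrame, covariates: list[str]) -> IpwModel:
    """Logistic assignment model and stabilized inverse-probability weights.

    The assignment probability is fitted by a binomial GLM with logit link
    (iteratively reweighted least squares, tolerance 1e-8) on dummy-coded
    categorical covariates.  Stabilized weights are (marginal arm share) /
    (fitted probability of the received arm).  Perfect separation is
    rejected with a diagnostic.
    """
    import warnings as _warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise ValueError(f"unknown covariates: {missing}")
    y = records["arm"].to_numpy(dtype=float)
    X = pd.get_dummies(records[covariates].astype(str), drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-8, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(f"perfect separation in the assignment model: {exc}") from exc
    except Exception as exc:  # other numerical failure
        raise ValueError(f"assignment model failed to converge: {exc}") from exc
    p = np.asarray(fit.mu)
    if np.any(p < 1e-10) or np.any(p > 1 - 1e-10):
        raise ValueError(
            "perfect separation: some fitted assignment probabilities are 0/1"
        )
    share = float(y.mean())
    w = np.where(y == 1, share / p, (1 - share) / (1 - p))
    ess = {
        a: float(w[y == a].sum() ** 2 / np.sum(w[y == a] ** 2)) for a in (0.0, 1.0)
    }
    return IpwModel(
        covariates=list(covariates),
        coefficients=fit.params,
        propensity=p,
        weights=w,
        diagnostics={
            "weight_min": float(w.min()),
            "weight_max": float(w.max()),
            "ess_control": ess[0.0],
            "ess_treated": ess[1.0],
            "converged": bool(fit.converged),
        },
    )


def covariate_balance(
    records: pd.DataFrame, covariates: list[str], weights: np.ndarray | None = None
) -> pd.DataFrame:
    """Total-variation distance of each arm's (weighted) covariate
    distribution from the pooled distribution — the IPW balance check."""
    w = np.ones(len(records)) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for c in covariates:
        pooled = records[c].value_counts(normalize=True)
        for a in (0, 1):
            m = (records["arm"] == a).to_numpy()
            wa = w[m]
            dist = (
                pd.Series(wa, index=records.loc[m, c].to_numpy()).groupby(level=0).sum()
                / wa.sum()
            )
            tv = 0.5 * sum(
                abs(dist.get(cat, 0.0) - pooled.get(cat, 0.0))
                for cat in set(dist.index) | set(pooled.index)
            )
            rows.append({"covariate": c, "arm": a, "tv_distance": float(tv)})
    return pd.DataFrame(rows)


def adjusted_rmst_compare(
    records: pd.DataFrame,
    ipw_model: IpwModel | None,
    tau: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    landmark_day: float | None = None,
    alpha: float = 0.05,
) -> RmstResult:
    """Weighted-KM RMST comparison with nonparametric bootstrap inference.

    With ``ipw_model=None`` (all weights one) the point estimates equal the
    unadjusted comparison exactly and the bootstrap still supplies the CIs
    — this is also the route for resampling-based CIs on unweighted
    contrasts.  Each bootstrap resample refits the assignment model, so the
    uncertainty of the weights is propagated.
    """
    if tau is None:
        tau = default_tau(records)
    weights = np.ones(len(records)) if ipw_model is None else ipw_model.weights
    y = records["arm"].to_numpy()
    for a in (0, 1):
        wa = weights[y == a]
        if wa.sum() ** 2 / np.sum(wa**2) < 10:
            raise ValueError(f"effective sample size below 10 in arm {a}")

    def _point(df: pd.DataFrame, w: np.ndarray) -> tuple[float, float]:
        out = []
        for a in (0, 1):
            sf = km_estimate(df, arm_filter=a, weights=w)
            out.append(rmst(sf, min(tau, sf.max_time))[0])
        return out[0], out[1]

    m0, m1 = _point(records, weights)

    rng = np.random.default_rng(seed)
    ratios, diffs = [], []
    idx_all = np.arange(len(records))
    failures = 0
    for _ in range(n_boot):
        idx = rng.choice(idx_all, size=len(idx_all), replace=True)
        df = records.iloc[idx].reset_index(drop=True)
        try:
            if ipw_model is None:
                w = np.ones(len(df))
            else:
                w = fit_ipw(df, ipw_model.covariates).weights
            b0, b1 = _point(df, w)
            ratios.append(b1 / b0)
            diffs.append(b1 - b0)
        except ValueError:
            failures += 1
    if failures > 0.2 * n_boot:
        raise ValueError(f"bootstrap unstable: {failures}/{n_boot} resamples failed")
    ratios = np.array(ratios)
    diffs = np.array(diffs)

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ratio = m1 / m0
    diff = m1 - m0
    se_log = float(np.std(np.log(ratios), ddof=1))
    se_diff = float(np.std(diffs, ddof=1))
    ratio_p = 2 * norm.sf(abs(np.log(ratio)) / se_log) if se_log > 0 else 1.0
    diff_p = 2 * norm.sf(abs(diff) / se_diff) if se_diff > 0 else 1.0

    return RmstResult(
        tau=tau,
        rmst_by_arm={0: m0, 1: m1},
        se_by_arm={0: float("nan"), 1: float("nan")},
        difference=diff,
        difference_ci=tuple(np.percentile(diffs, [lo, hi])),
        difference_p=float(diff_p),
        ratio=ratio,
        ratio_ci=tuple(np.percentile(ratios, [lo, hi])),
        ratio_p=float(ratio_p),
        landmark_day=landmark_day,
        weighting=UNADJUSTED if ipw_model is None else IPW,
        n_by_arm={a: int((y == a).sum()) for a in (0, 1)},
    )
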