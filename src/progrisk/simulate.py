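"""Two-arm trial simulator with a piecewise time-varying treatment effect.

The generator emulates a first-line maintenance-therapy trial: the control
arm progresses with a piecewise-constant hazard, and the treated arm's
hazard is the control hazard multiplied by a piecewise-constant relative
hazard r(t) — typically an early benefit (r < 1) that attenuates toward the
scheduled discontinuation of treatment and is followed by a period of excess
risk (r > 1), the "rebound" pattern.  Categorical covariates can shift both
the hazard and, optionally, the treatment-assignment odds, producing
measured confounding for the adjusted analyses to remove.

Event times are drawn exactly by inverse-CDF sampling: the cumulative
hazard of a piecewise-constant rate is piecewise linear and is inverted
segment by segment, so no discretization error enters the simulation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .series import DailySurvivalSeries, OBSERVED

DAYS_PER_MONTH = 365.0 / 12.0  # axis-label convention for month anchors


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardScenario:
    """Piecewise-constant control hazard and treated-arm relative hazard.

    ``control_rates`` and ``relative_hazard`` are sequences of
    ``(interval_start_day, value)`` pairs; each value applies from its start
    day until the next start day (the last interval extends to infinity).

    Attributes
    ----------
    control_rates
        Daily progression rate of the control arm per interval.
    relative_hazard
        Multiplier r(t) applied to the treated arm's hazard per interval.
    censor_rate
        Rate per day of independent exponential dropout censoring.
    admin_cutoff_day
        Administrative censoring horizon (end of follow-up).
    discontinuation_day
        Scheduled treatment-stop day (365 for a 12-month protocol).
    """

    control_rates: tuple[tuple[float, float], ...]
    relative_hazard: tuple[tuple[float, float], ...]
    censor_rate: float = 0.0
    admin_cutoff_day: float = np.inf
    discontinuation_day: float = 365.0

    def __post_init__(self):
        object.__setattr__(
            self, "control_rates", tuple((float(a), float(b)) for a, b in self.control_rates)
        )
        object.__setattr__(
            self, "relative_hazard", tuple((float(a), float(b)) for a, b in self.relative_hazard)
        )
        for name, pieces in (("control_rates", self.control_rates),
                             ("relative_hazard", self.relative_hazard)):
            if not pieces:
                raise ValueError(f"{name} must have at least one interval")
            starts = [s for s, _ in pieces]
            if starts[0] != 0:
                raise ValueError(f"{name}: first interval must start at day 0")
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise ValueError(f"{name}: interval starts must be strictly ascending")
        if any(r < 0 for _, r in self.control_rates):
            raise ValueError("control rates must be >= 0")
        if any(r <= 0 for _, r in self.relative_hazard):
            raise ValueError("relative hazard values must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if not self.admin_cutoff_day > 0:
            raise ValueError("admin_cutoff_day must be > 0")

    def arm_pieces(self, arm: int) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints and per-segment daily rates for one arm.

        Returns ``(breaks, rates)`` where ``rates[k]`` applies on
        ``[breaks[k], breaks[k+1])`` and the final segment extends to
        infinity.
        """
        ctrl_starts = np.array([s for s, _ in self.control_rates])
        ctrl_rates = np.array([r for _, r in self.control_rates])
        if arm == 0:
            return ctrl_starts, ctrl_rates
        rel_starts = np.array([s for s, _ in self.relative_hazard])
        rel_vals = np.array([r for _, r in self.relative_hazard])
        breaks = np.unique(np.concatenate([ctrl_starts, rel_starts]))
        i = np.searchsorted(ctrl_starts, breaks, side="right") - 1
        j = np.searchsorted(rel_starts, breaks, side="right") - 1
        return breaks, ctrl_rates[i] * rel_vals[j]

    def cumulative_hazard(self, arm: int, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear cumulative hazard of one arm at times ``t``."""
        breaks, rates = self.arm_pieces(arm)
        t = np.asarray(t, dtype=float)
        cum_at_break = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(breaks))])
        k = np.clip(np.searchsorted(breaks, t, side="right") - 1, 0, len(breaks) - 1)
        return cum_at_break[k] + rates[k] * (t - breaks[k])

    def to_dict(self) -> dict:
        d = asdict(self)
        if np.isinf(self.admin_cutoff_day):
            d["admin_cutoff_day"] = None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "HazardScenario":
        d = dict(d)
        if d.get("admin_cutoff_day") is None:
            d["admin_cutoff_day"] = np.inf
        d["control_rates"] = tuple(tuple(p) for p in d["control_rates"])
        d["relative_hazard"] = tuple(tuple(p) for p in d["relative_hazard"])
        return cls(**d)


@dataclass(frozen=True)
class CovariateModel:
    """Categorical covariates with hazard and assignment effects.

    Each covariate has category probabilities summing to one, per-category
    log-hazard effects (multiplying both arms' hazards) and per-category
    log-odds effects on treatment assignment (all zero in a randomized
    trial).  Effects default to zero for unlisted categories.
    """

    categories: Mapping[str, Mapping[str, float]]
    hazard_log_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    assignment_log_odds: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for name, probs in self.categories.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"covariate {name}: category probabilities sum to {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"covariate {name}: negative probability")
        for eff in (self.hazard_log_effects, self.assignment_log_odds):
            for name in eff:
                if name not in self.categories:
                    raise ValueError(f"effect given for unknown covariate {name}")

    @property
    def names(self) -> list[str]:
        return list(self.categories)

    def is_randomized(self) -> bool:
        return all(
            v == 0 for eff in self.assignment_log_odds.values() for v in eff.values()
        )

    def hazard_multiplier(self, row: Mapping[str, str]) -> float:
        log_m = 0.0
        for name, eff in self.hazard_log_effects.items():
            log_m += eff.get(row[name], 0.0)
        return float(np.exp(log_m))

    def assignment_logit(self, row: Mapping[str, str]) -> float:
        logit = 0.0
        for name, eff in self.assignment_log_odds.items():
            logit += eff.get(row[name], 0.0)
        return logit


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: the simulator's output and the KM input."""

    id: str
    time: float
    event: int
    arm: int
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.time > 0:
            raise ValueError("time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.arm not in (0, 1):
            raise ValueError("arm must be 0 or 1")


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Convert record objects to the canonical ``id,time,event,arm,...`` table."""
    rows = []
    for r in records:
        row = {"id": r.id, "time": r.time, "event": r.event, "arm": r.arm}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[SurvivalRecord]:
    cov_cols = [c for c in df.columns if c not in ("id", "time", "event", "arm")]
    return [
        SurvivalRecord(
            id=str(row["id"]),
            time=float(row["time"]),
            event=int(row["event"]),
            arm=int(row["arm"]),
            covariates={c: row[c] for c in cov_cols},
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _invert_cumhaz(breaks: np.ndarray, rates: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Solve Lambda(t) = target for piecewise-constant rates; inf if unreachable.

    The cumulative hazard is piecewise linear with knots at ``breaks``;
    ``searchsorted(side="right")`` lands on the last segment whose knot value
    is <= target, which skips flat (zero-rate) interior segments correctly.
    """
    targets = np.asarray(targets, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(breaks))])
    k = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(breaks) - 1)
    out = np.full(targets.shape, np.inf)
    ok = rates[k] > 0
    out[ok] = breaks[k[ok]] + (targets[ok] - cum[k[ok]]) / rates[k[ok]]
    return out


def sample_event_times(
    scenario: HazardScenario, arm: int, multipliers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF event times for subjects with given hazard multipliers."""
    breaks, rates = scenario.arm_pieces(arm)
    e = rng.exponential(size=len(multipliers))
    # Lambda(t) * m = e  <=>  Lambda(t) = e / m
    return _invert_cumhaz(breaks, rates, e / np.asarray(multipliers, dtype=float))


def simulate_trial(
    scenario: HazardScenario,
    covmodel: CovariateModel | None = None,
    n_per_arm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-arm trial; returns the ``id,time,event,arm,...`` table.

    Without assignment effects the trial is randomized 1:1 with exactly
    ``n_per_arm`` subjects per arm; with nonzero assignment log-odds the arm
    is Bernoulli given covariates and ``n_per_arm`` sets the expected size.
    Identical ``(scenario, covmodel, n_per_arm, seed)`` give identical output.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if (
        all(r == 0 for _, r in scenario.control_rates)
        and scenario.censor_rate == 0
        and np.isinf(scenario.admin_cutoff_day)
    ):
        raise ValueError("no event, censoring or cutoff possible: follow-up never ends")

    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm

    cov_frame = pd.DataFrame(index=range(n))
    multipliers = np.ones(n)
    if covmodel is not None:
        for name, probs in covmodel.categories.items():
            cats = list(probs)
            cov_frame[name] = rng.choice(cats, size=n, p=[probs[c] for c in cats])
        multipliers = np.array(
            [covmodel.hazard_multiplier(row) for row in cov_frame.to_dict("records")]
        )

    if covmodel is None or covmodel.is_randomized():
        arm = np.zeros(n, dtype=int)
        arm[rng.permutation(n)[:n_per_arm]] = 1
    else:
        logits = np.array(
            [covmodel.assignment_logit(row) for row in cov_frame.to_dict("records")]
        )
        arm = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)

    event_time = np.empty(n)
    for a in (0, 1):
        mask = arm == a
        event_time[mask] = sample_event_times(scenario, a, multipliers[mask], rng)

    if scenario.censor_rate > 0:
        censor = rng.exponential(1.0 / scenario.censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    censor = np.minimum(censor, scenario.admin_cutoff_day)

    time = np.minimum(event_time, censor)
    event = (event_time <= censor).astype(int)
    if np.any(~np.isfinite(time)):
        raise ValueError("infinite follow-up encountered; check scenario rates/cutoff")

    out = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "time": time,
            "event": event,
            "arm": arm,
        }
    )
    for c in cov_frame.columns:
        out[c] = cov_frame[c]
    return out


def true_survival(
    scenario: HazardScenario, arm: int, day_grid: Sequence[int] | np.ndarray
) -> DailySurvivalSeries:
    """Exact S(t) = exp(-Lambda(t)) of the scenario on an integer day grid."""
    day_grid = np.asarray(day_grid)
    if len(day_grid) == 0 or day_grid[0] < 0 or np.any(np.diff(day_grid) <= 0):
        raise ValueError("day_grid must be ascending and start at >= 0")
    S = np.exp(-scenario.cumulative_hazard(arm, day_grid.astype(float)))
    return DailySurvivalSeries(
        day=day_grid, S=S, provenance=np.full(len(day_grid), OBSERVED, dtype=object),
        label=f"arm{arm}-true",
    )


def true_relative_hazard(scenario: HazardScenario, day_grid: np.ndarray) -> np.ndarray:
    """r(t) evaluated on a day grid (oracle for recovery tests)."""
    starts = np.array([s for s, _ in scenario.relative_hazard])
    vals = np.array([v for _, v in scenario.relative_hazard])
    k = np.clip(np.searchsorted(starts, day_grid, side="right") - 1, 0, len(starts) - 1)
    return vals[k]


def marginal_true_rmst_ratio(
    scenario: HazardScenario,
    covmodel: CovariateModel | None,
    tau: float,
    landmark: float | None = None,
) -> float:
    """Exact counterfactual (marginal) RMST ratio treated/control up to ``tau``.

    Averages per-stratum restricted means over the population covariate
    distribution — the estimand a randomized trial (or a correctly adjusted
    analysis) targets.  With ``landmark`` set, returns the ratio of restricted
    means of the residual time among subjects event-free at the landmark.
    """

    def strata():
        if covmodel is None:
            yield 1.0, 1.0
            return
        names = covmodel.names
        for combo in itertools.product(*(covmodel.categories[n].keys() for n in names)):
            row = dict(zip(names, combo))
            p = np.prod([covmodel.categories[n][c] for n, c in row.items()])
            yield p, covmodel.hazard_multiplier(row)

    grid = np.linspace(0.0, tau, 4001)
    means = {}
    for a in (0, 1):
        base = scenario.cumulative_hazard(a, grid + (landmark or 0.0))
        num = den = 0.0
        for p, m in strata():
            S = np.exp(-base * m)
            if landmark:
                S0 = np.exp(-scenario.cumulative_hazard(a, np.array([landmark]))[0] * m)
                num += p * np.trapezoid(S / S0, grid) * S0
                den += p * S0
            else:
                num += p * np.trapezoid(S, grid)
                den += p
        means[a] = num / den
    return means[1] / means[0]


# ---------------------------------------------------------------------------
# shipped scenarios
# ---------------------------------------------------------------------------

def load_scenario(path_or_name) -> HazardScenario:
    """Load a scenario from a JSON file path or a packaged name."""
    try:
        with open(path_or_name) as fh:
            return HazardScenario.from_dict(json.load(fh))
    except (FileNotFoundError, IsADirectoryError):
        ref = resources.files("progrisk.data") / f"{path_or_name}.json"
        return HazardScenario.from_dict(json.loads(ref.read_text()))


def save_scenario(scenario: HazardScenario, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario.to_dict(), fh, indent=2)


def icon7_like_scenario() -> HazardScenario:
    """Default first-line scenario: benefit, attenuation by month 12, rebound.

    Control daily rate gives a median progression-free time of about 17
    months; r(t) steps 0.6 / 0.85 / 1.0 / 1.4 / 1.0 around a 12-month
    scheduled discontinuation.  These values reproduce the qualitative
    benefit-attenuation-rebound shape of first-line maintenance trials and
    are artifact defaults, not estimates from any real cohort.
    """
    return load_scenario("icon7_like")


def confounded_covariate_model() -> CovariateModel:
    """Demo covariate model with measured confounding of arm and hazard.

    Advanced stage and incomplete debulking both raise the progression
    hazard and the odds of receiving treatment, so the unadjusted arm
    contrast is biased against the treated arm until reweighted.
    """
    return CovariateModel(
        categories={
            "stage": {"early": 0.30, "advanced": 0.70},
            "debulk": {"complete": 0.70, "residual": 0.30},
            "age": {"lt65": 0.70, "ge65": 0.30},
            "histology": {"serous": 0.72, "nonserous": 0.28},
        },
        hazard_log_effects={
            "stage": {"advanced": 0.7},
            "debulk": {"residual": 0.5},
            "age": {"ge65": 0.2},
            "histology": {"nonserous": -0.2},
        },
        assignment_log_odds={
            "stage": {"advanced": 1.0},
            "debulk": {"residual": 0.6},
        },
    )


def randomized_covariate_model() -> CovariateModel:
    """Same covariates and hazard effects, zero assignment log-odds."""
    m = confounded_covariate_model()
    return CovariateModel(
        categories=m.categories,
        hazard_log_effects=m.hazard_log_effects,
        assignment_log_odds={},
    )


# ---------------------------------------------------------------------------
# KM-figure rasterization (fixture generator for the digitizer)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisSpec:
    """Pixel positions of the axis anchors used for calibration.

    x anchors are time 0 and ``x_anchor_months`` (12 or 24); y anchors are
    survival 0% and 100%.  Row 0 is the top of the image, so ``y100_px`` is
    normally smaller than ``y0_px``.
    """

    x0_px: float = 80.0
    x_anchor_px: float = 380.0
    x_anchor_months: float = 12.0
    y0_px: float = 650.0
    y100_px: float = 50.0

    def __post_init__(self):
        if self.x0_px == self.x_anchor_px or self.y0_px == self.y100_px:
            raise ValueError("axis anchor pixels must be distinct on each axis")

    @property
    def px_per_day(self) -> float:
        return (self.x_anchor_px - self.x0_px) / (self.x_anchor_months * DAYS_PER_MONTH)


def rasterize_km(
    series_by_arm: Mapping[object, DailySurvivalSeries],
    axis_spec: AxisSpec = AxisSpec(),
    image_size_px: tuple[int, int] = (1000, 700),
    jitter_px: float = 0.0,
    gap_spans: Sequence[tuple[float, float]] = (),
    seed: int = 0,
):
    """Emit per-arm pixel polylines as if traced from a published KM figure.

    One polyline point is produced per pixel column inside the plot box,
    sampling the step function at the day each column maps to.  ``jitter_px``
    adds uniform vertical noise (tracing error) and ``gap_spans`` deletes
    pixel-column intervals (occluded curve segments), exercising downstream
    gap filling.  Returns ``{arm: DigitizedCurve}``.
    """
    from .digitize import DigitizedCurve  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    width, height = image_size_px
    out = {}
    for arm, series in series_by_arm.items():
        cols = np.arange(int(np.ceil(axis_spec.x0_px)), width)
        days = (cols - axis_spec.x0_px) / axis_spec.px_per_day
        keep = days <= series.horizon
        cols, days = cols[keep], days[keep]
        for lo, hi in gap_spans:
            keep = (cols < lo) | (cols > hi)
            cols, days = cols[keep], days[keep]
        S = series.S[np.floor(days).astype(int)]
        py = axis_spec.y0_px + S * (axis_spec.y100_px - axis_spec.y0_px)
        if jitter_px > 0:
            py = py + rng.uniform(-jitter_px, jitter_px, size=len(py))
        py = np.clip(np.rint(py), 0, height - 1)
        out[arm] = DigitizedCurve(
            polyline=np.column_stack([cols.astype(float), py]),
            x_calibration=((axis_spec.x0_px, 0.0),
                           (axis_spec.x_anchor_px, axis_spec.x_anchor_months)),
            y_calibration=((axis_spec.y0_px, 0.0), (axis_spec.y100_px, 1.0)),
            label=str(series.label or arm),
        )
    return out
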