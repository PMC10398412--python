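"""Per-day survival series: the common currency between the simulator,
the product-limit estimator, the figure digitizer, and the risk curves.

A :class:`DailySurvivalSeries` holds the survival fraction on an integer
day grid ``0..horizon`` together with a per-day provenance flag saying
whether the value was directly observed, filled in across a gap, or
carried forward past the end of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: provenance codes
OBSERVED = "observed"
INTERPOLATED = "interpolated"
EXTRAPOLATED = "extrapolated"

_VALID_PROVENANCE = {OBSERVED, INTERPOLATED, EXTRAPOLATED}


@dataclass
class DailySurvivalSeries:
    """Survival fraction evaluated on every integer day of ``0..horizon``.

    Parameters
    ----------
    day
        Integer days, ``0, 1, ..., horizon``.
    S
        Survival fraction per day, non-increasing, in ``[0, 1]``.
    provenance
        Per-day flag: ``observed``, ``interpolated`` or ``extrapolated``.
    label
        Free-text arm / source label.
    """

    day: np.ndarray
    S: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        self.S = np.asarray(self.S, dtype=float)
        if self.provenance is None:
            self.provenance = np.full(self.day.shape, OBSERVED, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if self.day.ndim != 1 or self.day.shape != self.S.shape:
            raise ValueError("day and S must be 1-d arrays of equal length")
        if self.provenance.shape != self.day.shape:
            raise ValueError("provenance must align with the day grid")
        if len(self.day) == 0:
            raise ValueError("empty series")
        if self.day[0] < 0 or np.any(np.diff(self.day) <= 0):
            raise ValueError("day grid must be ascending and start at >= 0")
        bad = set(self.provenance) - _VALID_PROVENANCE
        if bad:
            raise ValueError(f"unknown provenance codes: {bad}")
        if np.any(self.S < -1e-12) or np.any(self.S > 1 + 1e-12):
            raise ValueError("S must lie in [0, 1]")
        if np.any(np.diff(self.S) > 1e-9):
            raise ValueError("S must be non-increasing")

    @property
    def horizon(self) -> int:
        return int(self.day[-1])

    def is_daily(self) -> bool:
        """True when the grid is every integer day 0..horizon."""
        return self.day[0] == 0 and bool(np.all(np.diff(self.day) == 1))

    def value_at(self, day: int) -> float:
        """Survival fraction at an integer day on the grid."""
        idx = np.searchsorted(self.day, day)
        if idx == len(self.day) or self.day[idx] != day:
            raise ValueError(f"day {day} not on the grid")
        return float(self.S[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "S": self.S, "provenance": self.provenance}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "DailySurvivalSeries":
        df = pd.read_csv(path)
        return cls(
            day=df["day"].to_numpy(),
            S=df["S"].to_numpy(),
            provenance=df["provenance"].to_numpy(dtype=object),
            label=label,
        )
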