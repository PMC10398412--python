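"""Calibrate extracted Kaplan-Meier figure coordinates into per-day survival.

Input is a pixel polyline traced along one published KM curve (as produced
by ImageJ-style point extraction, or by :func:`progrisk.simulate.rasterize_km`
in tests) together with axis-calibration pixels: the x positions of time 0
and of the 12- or 24-month tick, and the y positions of the 0% and 100%
gridlines.  Output is survival evaluated on every integer day with a
per-day provenance flag, so the effect of gap filling and monotonicity
repair on downstream risk curves can be audited.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import DailySurvivalSeries, EXTRAPOLATED, INTERPOLATED, OBSERVED
from .simulate import DAYS_PER_MONTH


@dataclass(frozen=True)
class DigitizedCurve:
    """Pixel polyline plus axis calibration for one traced KM curve.

    ``x_calibration`` holds ``((px, months), (px, months))`` anchor pairs
    (months 0 and 12 or 24); ``y_calibration`` holds ``((py, fraction),
    (py, fraction))`` for survival 0% and 100%.
    """

    polyline: np.ndarray
    x_calibration: tuple[tuple[float, float], tuple[float, float]]
    y_calibration: tuple[tuple[float, float], tuple[float, float]]
    label: str = ""

    def __post_init__(self):
        poly = np.asarray(self.polyline, dtype=float)
        object.__setattr__(self, "polyline", poly)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
            raise ValueError("polyline must be an (n>=2, 2) array of pixels")
        (xa, _), (xb, _) = self.x_calibration
        (ya, _), (yb, _) = self.y_calibration
        if xa == xb or ya == yb:
            raise ValueError("calibration pixels coincide on an axis")

    def to_files(self, csv_path, json_path) -> None:
        pd.DataFrame(self.polyline, columns=["px", "py"]).to_csv(csv_path, index=False)
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "x_calibration": [list(p) for p in self.x_calibration],
                    "y_calibration": [list(p) for p in self.y_calibration],
                    "label": self.label,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_files(cls, csv_path, json_path) -> "DigitizedCurve":
        poly = pd.read_csv(csv_path)[["px", "py"]].to_numpy()
        with open(json_path) as fh:
            meta = json.load(fh)
        return cls(
            polyline=poly,
            x_calibration=tuple(tuple(p) for p in meta["x_calibration"]),
            y_calibration=tuple(tuple(p) for p in meta["y_calibration"]),
            label=meta.get("label", ""),
        )


@dataclass(frozen=True)
class Calibration:
    """Affine pixel -> (day, survival fraction) maps from axis anchors."""

    day_per_px: float
    day_at_zero_px: float  # day value of pixel column 0
    frac_per_px: float
    frac_at_zero_px: float

    def px_to_day(self, px):
        return self.day_at_zero_px + self.day_per_px * np.asarray(px, dtype=float)

    def py_to_frac(self, py):
        return self.frac_at_zero_px + self.frac_per_px * np.asarray(py, dtype=float)


def calibrate(curve: DigitizedCurve) -> Calibration:
    """Build the linear axis maps; month anchors use 365/12 days per month."""
    (x0, m0), (x1, m1) = curve.x_calibration
    (y0, f0), (y1, f1) = curve.y_calibration
    d0, d1 = m0 * DAYS_PER_MONTH, m1 * DAYS_PER_MONTH
    day_per_px = (d1 - d0) / (x1 - x0)
    frac_per_px = (f1 - f0) / (y1 - y0)
    return Calibration(
        day_per_px=day_per_px,
        day_at_zero_px=d0 - day_per_px * x0,
        frac_per_px=frac_per_px,
        frac_at_zero_px=f0 - frac_per_px * y0,
    )


def to_daily_series(
    curve: DigitizedCurve, horizon_day: int, label: str | None = None
) -> DailySurvivalSeries:
    """Calibrated per-day survival with gap filling and monotonicity repair.

    Days covered by the polyline use previous-value (step) interpolation;
    spans where consecutive points are more than ~3x the median sampling
    interval apart are bridged linearly and flagged ``interpolated`` (the
    automated stand-in for manually completing occluded curve segments);
    days past the last point carry the last value, flagged ``extrapolated``.
    Any survival increase left by tracing noise is removed by a running
    minimum, and the series is clipped to [0, 1].  S(0) is snapped to 1
    when the traced start is within 2% of 1, and left (with a warning)
    otherwise.
    """
    cal = calibrate(curve)
    day = cal.px_to_day(curve.polyline[:, 0])
    frac = cal.py_to_frac(curve.polyline[:, 1])
    order = np.argsort(day, kind="stable")
    day, frac = day[order], frac[order]

    inside = (day >= -1.0) & (day <= horizon_day + 1.0) & (frac >= -0.1) & (frac <= 1.1)
    if not inside.any():
        raise ValueError("digitized polyline lies entirely outside the plot box")
    day, frac = day[inside], frac[inside]

    spacing = np.diff(day)
    med = np.median(spacing[spacing > 0]) if np.any(spacing > 0) else 1.0
    gap_threshold = max(3.0, 3.0 * med)

    grid = np.arange(horizon_day + 1)
    idx = np.searchsorted(day, grid, side="right") - 1
    S = np.empty(len(grid))
    prov = np.empty(len(grid), dtype=object)
    last = len(day) - 1
    for g, i in enumerate(idx):
        if i < 0:  # before the first traced point
            S[g] = frac[0]
            prov[g] = OBSERVED if day[0] - grid[g] <= 1.0 else INTERPOLATED
        elif i == last:
            S[g] = frac[last]
            prov[g] = EXTRAPOLATED if grid[g] > day[last] else OBSERVED
        elif day[i + 1] - day[i] > gap_threshold and grid[g] > day[i]:
            w = (grid[g] - day[i]) / (day[i + 1] - day[i])
            S[g] = frac[i] * (1 - w) + frac[i + 1] * w
            prov[g] = INTERPOLATED
        else:
            S[g] = frac[i]
            prov[g] = OBSERVED

    if abs(S[0] - 1.0) <= 0.02:
        S[0] = 1.0
    else:
        warnings.warn(
            f"digitized curve starts at S(0)={S[0]:.3f}, more than 2% from 1; "
            "left unchanged",
            stacklevel=2,
        )
    S = np.clip(np.minimum.accumulate(S), 0.0, 1.0)
    return DailySurvivalSeries(
        day=grid, S=S, provenance=prov,
        label=label if label is not None else curve.label,
    )
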