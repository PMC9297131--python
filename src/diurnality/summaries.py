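"""Circular summaries of fitted diurnal curves.

From a fitted model's trigonometric coefficients and intercept we form, per
day type, the fitted 24-hour mean curve on a 1-minute grid (the reporting
resolution for peak times) and reduce it to:

* the **circular median occurrence time** — the clock time minimizing the
  weighted mean arc distance on the 24-hour circle, where the weights are the
  min-subtracted curve treated as a nonnegative density.  Min-subtraction
  makes the statistic baseline-invariant and peak-seeking: for a unimodal
  curve the circular median sits at the peak;
* the **amplitude-to-mean ratio (AMR)** — (peak - trough) / mean, a unitless
  measure of diurnal cyclic strength (0 for a flat curve);
* the **weekend-weekday AMR contrast** — difference of the two amplitudes
  divided by the average of the two means; negative values mean stronger
  weekday cyclicity.

Clock-time differences use the shorter arc and are bucketed into 2-hour bands
for tabulation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model import FittedModel

__all__ = [
    "GRID_MINUTES",
    "DiurnalCurve",
    "DiurnalSummary",
    "UndefinedStatisticError",
    "minute_grid",
    "diurnal_curve",
    "amplitude_mean_ratio",
    "circular_median_time",
    "circular_median_from_values",
    "amr_contrast",
    "amr_contrast_from_curves",
    "circular_difference",
    "median_diff_band",
    "polar_normalize",
    "format_clock",
]

#: Grid resolution (minutes) for evaluating diurnal curves; peak times are
#: reported to the minute.
GRID_MINUTES = 1


class UndefinedStatisticError(ValueError):
    """The requested summary is undefined for this curve (e.g. flat curve)."""


def minute_grid(minutes: int = GRID_MINUTES) -> np.ndarray:
    """Clock-time grid on [0, 24) in hours, with ``minutes`` spacing."""
    return np.arange(0.0, 24.0, minutes / 60.0)


@dataclass
class DiurnalCurve:
    """Fitted mean RSV as a pure function of clock time for one day type."""

    daytype: str
    grid: np.ndarray    # hours on [0, 24)
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def amplitude(self) -> float:
        """Peak-to-trough range."""
        return float(np.max(self.values) - np.min(self.values))


def diurnal_curve(model: "FittedModel", daytype: str,
                  minutes: int = GRID_MINUTES) -> DiurnalCurve:
    """Fitted diurnal curve for one day type on the minute grid.

    The curve is intercept + trend evaluated at the study-midpoint day
    (+ weekend level for the weekend curve) + the day type's eight
    trigonometric terms, making it a pure function of clock time.
    """
    from .simulate import OMEGA

    if daytype not in ("weekday", "weekend"):
        raise ValueError("daytype must be 'weekday' or 'weekend'")
    t = minute_grid(minutes)
    level = model.intercept + model.trend_level_mid
    if daytype == "weekend":
        level += model.weekend_level
    values = np.full_like(t, level)
    for n in (1, 2, 3, 4):
        values = values + model.harmonic_coef(daytype, n, "cos") * np.cos(n * OMEGA * t)
        values = values + model.harmonic_coef(daytype, n, "sin") * np.sin(n * OMEGA * t)
    return DiurnalCurve(daytype=daytype, grid=t, values=values)


def amplitude_mean_ratio(curve: DiurnalCurve) -> float:
    """(peak - trough) / mean of the fitted daily curve."""
    mean = curve.mean
    if mean <= 0:
        raise UndefinedStatisticError("amplitude-to-mean ratio needs a positive mean")
    return curve.amplitude / mean


@functools.lru_cache(maxsize=4)
def _arc_distance_matrix(size: int) -> np.ndarray:
    """Pairwise shorter-arc distances (hours) between grid points on the circle."""
    idx = np.arange(size)
    diff = np.abs(idx[:, None] - idx[None, :])
    diff = np.minimum(diff, size - diff)
    return diff * (24.0 / size)


def circular_median_from_values(values: np.ndarray, grid: np.ndarray) -> float:
    """Weighted circular median of a curve sampled on an even circular grid.

    The curve minimum is subtracted and the remainder used as nonnegative
    weights; the median is the grid point minimizing the weighted mean arc
    distance, ties broken by earliest clock time. ``values`` may be a matrix
    (grid x replicates), in which case one median per column is returned.
    """
    values = np.asarray(values, dtype=float)
    one = values.ndim == 1
    V = values[:, None] if one else values
    W = V - V.min(axis=0, keepdims=True)
    totals = W.sum(axis=0)
    if np.any(totals <= 0):
        raise UndefinedStatisticError("circular median undefined for a constant curve")
    D = _arc_distance_matrix(len(grid))
    scores = D @ W
    idx = np.argmin(scores, axis=0)  # first minimum = earliest clock time
    med = grid[idx]
    return float(med[0]) if one else med


def circular_median_time(curve: DiurnalCurve) -> float:
    """Circular median occurrence time (hours on [0, 24)) of a fitted curve."""
    return circular_median_from_values(curve.values, curve.grid)


def amr_contrast_from_curves(weekday: DiurnalCurve, weekend: DiurnalCurve) -> float:
    """Weekend-minus-weekday amplitude difference over the average of the means."""
    avg_mean = 0.5 * (weekday.mean + weekend.mean)
    if avg_mean <= 0:
        raise UndefinedStatisticError("AMR contrast needs a positive average mean")
    return (weekend.amplitude - weekday.amplitude) / avg_mean


def amr_contrast(model: "FittedModel") -> float:
    """AMR contrast computed from a fitted model's two day-type curves.

    Negative values indicate stronger weekday cyclic strength.
    """
    return amr_contrast_from_curves(diurnal_curve(model, "weekday"),
                                    diurnal_curve(model, "weekend"))


def circular_difference(h1: float, h2: float) -> float:
    """Signed shorter-arc difference h2 - h1 in hours, in (-12, 12]."""
    d = (float(h2) - float(h1)) % 24.0
    return d - 24.0 if d > 12.0 else d


def median_diff_band(m1: float, m2: float) -> str:
    """Bucket the circular absolute difference of two clock times into 2-h bands.

    Bands are ``0-2``, ``2-4``, ..., ``10-12`` (the shorter arc never exceeds
    12 hours).
    """
    d = abs(circular_difference(m1, m2))
    lo = min(int(d // 2) * 2, 10)
    return f"{lo}-{lo + 2}"


def polar_normalize(hourly_means: np.ndarray) -> np.ndarray:
    """Divide hourly means by their minimum so the flattest hour maps to 1.0."""
    v = np.asarray(hourly_means, dtype=float)
    m = v.min()
    if m <= 0:
        raise UndefinedStatisticError("polar normalization needs a positive minimum")
    return v / m


def format_clock(hours: float) -> str:
    """Render fractional hours on [0, 24) as an ``HH:MM`` clock string."""
    total = int(round(float(hours) % 24.0 * 60.0)) % (24 * 60)
    return f"{total // 60:02d}:{total % 60:02d}"


@dataclass
class DiurnalSummary:
    """Machine-readable analogue of one summary-table row for a search term."""

    term: str
    circular_median: dict[str, float]        # daytype -> hours on [0, 24)
    amr: dict[str, float]                    # daytype -> ratio
    amr_contrast: float
    median_diff_band: str
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_value: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0
    degenerate: bool = False

    def to_row(self) -> dict:
        """Flatten to a table row with clock-formatted medians and CIs."""
        row: dict = {"term": self.term}
        for daytype in ("weekday", "weekend"):
            row[f"median_{daytype}"] = format_clock(self.circular_median[daytype])
            lo, hi = self.ci.get(f"median_{daytype}", (np.nan, np.nan))
            row[f"median_{daytype}_ci"] = (
                f"({format_clock(lo)}, {format_clock(hi)})" if np.isfinite(lo) else "")
        row["median_diff_band"] = self.median_diff_band
        for daytype in ("weekday", "weekend"):
            row[f"amr_{daytype}"] = round(self.amr[daytype], 4)
            lo, hi = self.ci.get(f"amr_{daytype}", (np.nan, np.nan))
            row[f"amr_{daytype}_ci"] = (
                f"({lo:.4f}, {hi:.4f})" if np.isfinite(lo) else "")
        row["amr_contrast"] = round(self.amr_contrast, 4)
        lo, hi = self.ci.get("amr_contrast", (np.nan, np.nan))
        row["amr_contrast_ci"] = f"({lo:.4f}, {hi:.4f})" if np.isfinite(lo) else ""
        for daytype in ("weekday", "weekend"):
            p = self.p_value.get(f"diurnality_{daytype}", np.nan)
            row[f"p_{daytype}"] = f"{p:.3g}" if np.isfinite(p) else ""
        return row
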