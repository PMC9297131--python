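"""Regressor blocks for the Serfling-type model of hourly search volume.

Three blocks:

* **trend** — degree 1-3 orthogonal polynomials in elapsed days (the constant
  is carried by the model intercept), orthonormalized on the observed rows;
* **harmonics** — sin/cos pairs of the 24-hour cycle and its first three
  overtones (``omega = 2*pi/24``, orders n = 1..4), built separately for
  weekdays and weekend days, plus a weekend level column so the weekend
  curve's mean — not just its shape — is free;
* **nuisance** — 0/1 interval indicators ``1{k*m <= x <= k*(m+1)-1}`` over
  elapsed hours x for a ladder of widths k, the candidate outlier/epidemic
  terms the LASSO filter selects from.

For each width k the indicator columns partition the time axis (the truncated
final window is kept), so their rowwise sum is exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import OMEGA

__all__ = [
    "WIDTH_PRESETS",
    "TrendBasis",
    "DesignMatrices",
    "build_trend_basis",
    "build_harmonic_basis",
    "build_nuisance_basis",
    "HARMONIC_ORDERS",
    "harmonic_column_names",
]

#: Interval-width ladders for the nuisance basis. ``default`` is the primary
#: set; the two sensitivity sets exist to show the choice hardly matters.
WIDTH_PRESETS: dict[str, tuple[int, ...]] = {
    "default": (8, 16, 32, 64, 128, 168),
    "sensitivity_a": (7, 14, 28, 56, 112, 168),
    "sensitivity_b": (9, 18, 36, 72, 144, 168),
}

HARMONIC_ORDERS = (1, 2, 3, 4)
DAYTYPES = ("weekday", "weekend")


class RankError(ValueError):
    """Not enough distinct support points to build the requested basis."""


@dataclass
class TrendBasis:
    """Orthonormal cubic polynomial basis fitted to a set of elapsed days.

    Built by QR decomposition of the Vandermonde matrix of centered/scaled
    elapsed days; the mapping is stored so the basis can be evaluated at
    arbitrary new times (e.g. the study midpoint when forming diurnal curves).
    """

    center: float
    scale: float
    r_inv: np.ndarray  # (4, 4) map from raw Vandermonde to orthonormal columns

    @classmethod
    def fit(cls, elapsed_days: np.ndarray) -> tuple["TrendBasis", np.ndarray]:
        d = np.asarray(elapsed_days, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("elapsed_days must be finite")
        if len(np.unique(d)) < 4:
            raise RankError("need at least 4 distinct elapsed-day values for a cubic trend")
        center = float(d.mean())
        scale = float(d.std()) or 1.0
        dc = (d - center) / scale
        V = np.column_stack([np.ones_like(dc), dc, dc**2, dc**3])
        Q, R = np.linalg.qr(V)
        # fix signs so each column correlates positively with its raw power
        signs = np.sign(np.diag(R))
        signs[signs == 0] = 1.0
        Q = Q * signs
        R = R * signs[:, None]
        basis = cls(center=center, scale=scale, r_inv=np.linalg.inv(R))
        return basis, Q[:, 1:]

    def transform(self, elapsed_days: np.ndarray) -> np.ndarray:
        """Evaluate the 3 trend columns at new elapsed-day values."""
        d = np.asarray(elapsed_days, dtype=float)
        dc = (d - self.center) / self.scale
        V = np.column_stack([np.ones_like(dc), dc, dc**2, dc**3])
        return (V @ self.r_inv)[:, 1:]


def build_trend_basis(elapsed_days: np.ndarray) -> np.ndarray:
    """Degree 1-3 orthonormal polynomial columns on the observed rows."""
    _, Q = TrendBasis.fit(elapsed_days)
    return Q


def harmonic_column_names() -> list[str]:
    names = []
    for daytype in DAYTYPES:
        for n in HARMONIC_ORDERS:
            names.append(f"{daytype}_sin{n}")
            names.append(f"{daytype}_cos{n}")
    names.append("weekend_level")
    return names


def build_harmonic_basis(hour_of_day: np.ndarray,
                         is_weekend: np.ndarray) -> np.ndarray:
    """Day-type-specific trigonometric columns plus the weekend level.

    Column order matches :func:`harmonic_column_names`: weekday sin/cos pairs
    for n = 1..4, then weekend pairs, then the 0/1 weekend indicator. A
    weekday row is exactly zero in all weekend columns and vice versa.
    """
    t = np.asarray(hour_of_day, dtype=float)
    if np.any((t < 0) | (t > 23)):
        raise ValueError("hour_of_day must lie in 0..23")
    we = np.asarray(is_weekend, dtype=bool)
    masks = {"weekday": ~we, "weekend": we}
    cols = []
    for daytype in DAYTYPES:
        m = masks[daytype].astype(float)
        for n in HARMONIC_ORDERS:
            cols.append(m * np.sin(n * OMEGA * t))
            cols.append(m * np.cos(n * OMEGA * t))
    cols.append(we.astype(float))
    return np.column_stack(cols)


def build_nuisance_basis(n_hours, widths: Sequence[int]
                         ) -> tuple[sp.csc_matrix, list[tuple[int, int]]]:
    """0/1 interval indicators over elapsed hours, one column per (k, m).

    ``n_hours`` may be an integer (rows at hours 0..n_hours-1) or a vector of
    observed elapsed hours (rows with gaps). For each width k, windows
    m = 0, 1, ... tile the axis; column (k, m) is one on hours
    k*m <= x <= k*(m+1)-1. Returns the sparse matrix and the (k, m) metadata
    aligned with its columns.
    """
    if np.isscalar(n_hours):
        x = np.arange(int(n_hours), dtype=np.int64)
    else:
        x = np.asarray(n_hours, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("empty hour grid")
    span = int(x.max()) + 1
    widths = sorted(set(int(k) for k in widths))
    if any(k <= 0 for k in widths):
        raise ValueError("indicator widths must be positive")
    if max(widths) > span:
        raise ValueError(f"max width {max(widths)} exceeds series span {span}")

    n = len(x)
    meta: list[tuple[int, int]] = []
    rows, cols = [], []
    col = 0
    for k in widths:
        window = x // k  # m index of every row for this width
        n_windows = int(np.ceil(span / k))
        for m in range(n_windows):
            idx = np.flatnonzero(window == m)
            rows.append(idx)
            cols.append(np.full(len(idx), col, dtype=np.int64))
            meta.append((k, m))
            col += 1
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(len(rows), dtype=float)
    mat = sp.csc_matrix((data, (rows, cols)), shape=(n, col))
    return mat, meta


@dataclass
class DesignMatrices:
    """The three regressor blocks of the model, with column metadata."""

    trend: np.ndarray                      # n x 3, orthonormal
    harmonic: np.ndarray                   # n x 17
    nuisance: sp.csc_matrix                # n x K, 0/1
    nuisance_meta: list[tuple[int, int]]   # (width k, window m) per column
    harmonic_names: list[str]
    trend_basis: TrendBasis
    elapsed_days: np.ndarray
    hour_of_day: np.ndarray
    is_weekend: np.ndarray
    widths: tuple[int, ...]
    _workspace: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.trend.shape[0]

    @property
    def unpenalized(self) -> np.ndarray:
        """Intercept + trend + harmonic columns (never penalized)."""
        key = "unpenalized"
        if key not in self._workspace:
            self._workspace[key] = np.column_stack(
                [np.ones(self.n), self.trend, self.harmonic])
        return self._workspace[key]

    @classmethod
    def from_annotations(cls, frame: pd.DataFrame,
                         widths: Sequence[int] | str = "default") -> "DesignMatrices":
        """Build all blocks from a locally-annotated series frame.

        ``widths`` is a preset name (``default``, ``sensitivity_a``,
        ``sensitivity_b``) or an explicit collection of interval widths.
        """
        if isinstance(widths, str):
            try:
                widths = WIDTH_PRESETS[widths]
            except KeyError:
                raise ValueError(
                    f"unknown width preset {widths!r}; "
                    f"choose from {sorted(WIDTH_PRESETS)}") from None
        widths = tuple(sorted(set(int(k) for k in widths)))
        required = ("elapsed_days", "hour_of_day", "is_weekend", "elapsed_hours")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks annotation column(s) {missing}; "
                             "run to_local_time first")
        days = frame["elapsed_days"].to_numpy(dtype=float)
        tb, trend = TrendBasis.fit(days)
        harmonic = build_harmonic_basis(frame["hour_of_day"].to_numpy(),
                                        frame["is_weekend"].to_numpy())
        nuisance, meta = build_nuisance_basis(
            frame["elapsed_hours"].to_numpy(), widths)
        return cls(trend=trend, harmonic=harmonic, nuisance=nuisance,
                   nuisance_meta=meta, harmonic_names=harmonic_column_names(),
                   trend_basis=tb, elapsed_days=days,
                   hour_of_day=frame["hour_of_day"].to_numpy(),
                   is_weekend=frame["is_weekend"].to_numpy(dtype=bool),
                   widths=widths)
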