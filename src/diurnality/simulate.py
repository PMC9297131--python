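"""Synthetic Google-Trends-like hourly RSV series with known ground truth.

The generator mirrors every component of the analysis model so each downstream
stage has a recovery-testable input: a smooth cubic trend, weekday- and
weekend-specific diurnal harmonics (orders 1-4), additive Gaussian sampling
noise clipped at zero, additive boxcar outlier surges (the exact shape the
interval-indicator nuisance basis is built to absorb), and an optional
per-week rescaling that emulates Trends returning each weekly request window
scaled independently to a max of 100.

Ground-truth diurnal summaries (circular medians, amplitude-to-mean ratios)
are computed by running the package's own circular-summary operations on the
noiseless day-type curves, so truth and estimate share one set of numerical
conventions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import HourlySeries, to_local_time


@functools.lru_cache(maxsize=8)
def _annotated_shell(start: str, n_hours: int) -> "HourlySeries":
    """Annotated zero-valued series on the (start, n_hours) hourly grid.

    The calendar annotation depends only on the grid, so repeated simulation
    runs (parameter sweeps, coverage studies) share one shell.
    """
    index = pd.date_range(start, periods=n_hours, freq="h", tz="UTC")
    frame = pd.DataFrame({"rsv": np.zeros(n_hours)}, index=index)
    shell = HourlySeries(term="shell", location="SIM", replicate=-1,
                         frame=frame, is_raw=False)
    return to_local_time(shell, "UTC")

__all__ = [
    "OMEGA",
    "Harmonic",
    "Surge",
    "SyntheticSpec",
    "GroundTruth",
    "phase_for_peak",
    "simulate_series",
    "apply_weekly_rescale",
]

#: Angular frequency of the 24-hour cycle (radians per hour).
OMEGA = 2.0 * np.pi / 24.0

#: Hours in one Trends request window.
WEEK_HOURS = 168

#: Length of the study year 2018 in hours.
YEAR_HOURS = 8760

TREND_DAY_SCALE = 365.0  # trend cubic is parameterized in years-elapsed


@dataclass(frozen=True)
class Harmonic:
    """One diurnal Fourier component: amplitude * cos(n*omega*t - phase)."""

    n: int
    amplitude: float
    phase: float  # radians in [0, 2*pi)

    def __post_init__(self) -> None:
        if not 1 <= self.n <= 4:
            raise ValueError("harmonic order must be in 1..4")
        object.__setattr__(self, "phase", float(self.phase) % (2 * np.pi))

    @property
    def cos_coef(self) -> float:
        """Coefficient of cos(n*omega*t) in the expanded form."""
        return self.amplitude * np.cos(self.phase)

    @property
    def sin_coef(self) -> float:
        """Coefficient of sin(n*omega*t) in the expanded form."""
        return self.amplitude * np.sin(self.phase)


def phase_for_peak(n: int, peak_hour: float) -> float:
    """Phase (radians) putting the n-th harmonic's crest at ``peak_hour``."""
    return (n * OMEGA * peak_hour) % (2 * np.pi)


@dataclass(frozen=True)
class Surge:
    """Additive boxcar outlier: +magnitude on hours [start, start+duration)."""

    start_hour: int
    duration_hours: int
    magnitude: float

    def __post_init__(self) -> None:
        if self.duration_hours < 1:
            raise ValueError("surge duration must be >= 1 hour")


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic hourly RSV series.

    Defaults describe a plausible eye-condition search term over the full
    year 2018: baseline RSV 50 with a gentle cubic drift of a few RSV units,
    a morning-peaked weekday rhythm (fundamental amplitude 15, peak 05:00,
    plus a second harmonic sharpening the peak), a weaker later-peaking
    weekend rhythm, and hour-to-hour sampling noise of SD 5 (about 10% of the
    baseline, the scale of replicate-to-replicate scatter seen in Trends
    downloads).
    """

    n_hours: int = YEAR_HOURS
    baseline: float = 50.0
    trend_coeffs: tuple[float, float, float] = (5.0, -3.0, 2.0)
    weekday_harmonics: tuple[Harmonic, ...] = (
        Harmonic(1, 15.0, phase_for_peak(1, 5.0)),
        Harmonic(2, 4.0, phase_for_peak(2, 2.0)),
    )
    weekend_harmonics: tuple[Harmonic, ...] = (
        Harmonic(1, 12.0, phase_for_peak(1, 7.0)),
    )
    weekend_level: float = 0.0
    noise_sd: float = 5.0
    outliers: tuple[Surge, ...] = ()
    per_week_rescale: bool = False
    seed: int = 0
    start: str = "2018-01-01"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_hours < 1:
            raise ValueError("n_hours must be positive")
        self.weekday_harmonics = tuple(
            h if isinstance(h, Harmonic) else Harmonic(*h) for h in self.weekday_harmonics
        )
        self.weekend_harmonics = tuple(
            h if isinstance(h, Harmonic) else Harmonic(*h) for h in self.weekend_harmonics
        )
        self.outliers = tuple(
            s if isinstance(s, Surge) else Surge(*s) for s in self.outliers
        )

    def trend(self, elapsed_days: np.ndarray) -> np.ndarray:
        """Cubic trend evaluated at elapsed days (parameterized in years)."""
        u = np.asarray(elapsed_days, dtype=float) / TREND_DAY_SCALE
        c1, c2, c3 = self.trend_coeffs
        return c1 * u + c2 * u**2 + c3 * u**3

    def daytype_curve(self, daytype: str, t: np.ndarray,
                      elapsed_days_ref: float) -> np.ndarray:
        """Noiseless diurnal curve for one day type at clock times ``t`` (hours)."""
        harmonics = (self.weekday_harmonics if daytype == "weekday"
                     else self.weekend_harmonics)
        level = self.baseline + float(self.trend(np.array([elapsed_days_ref]))[0])
        if daytype == "weekend":
            level += self.weekend_level
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, level)
        for h in harmonics:
            out = out + h.amplitude * np.cos(h.n * OMEGA * t - h.phase)
        return out


@dataclass
class GroundTruth:
    """True generative quantities recorded alongside a simulated series."""

    spec: SyntheticSpec
    mean_curve: np.ndarray            # noiseless, outlier-free hourly mean
    outlier_signal: np.ndarray        # additive boxcar component per hour
    weekday_curve: np.ndarray         # noiseless diurnal curve on the minute grid
    weekend_curve: np.ndarray
    grid: np.ndarray                  # clock-time grid (hours) for the curves
    circular_median: dict = field(default_factory=dict)   # daytype -> hours
    amr: dict = field(default_factory=dict)               # daytype -> ratio
    amr_contrast: float = float("nan")
    harmonic_coefs: dict = field(default_factory=dict)    # (daytype, n, fn) -> coef


def _true_summaries(truth: GroundTruth) -> None:
    # Computed with the package's circular-summary operations (one set of
    # numerical conventions for truth and estimate). Import here to avoid a
    # cycle at module load.
    from . import summaries

    for daytype, values in (("weekday", truth.weekday_curve),
                            ("weekend", truth.weekend_curve)):
        curve = summaries.DiurnalCurve(daytype=daytype, grid=truth.grid, values=values)
        if np.ptp(values) > 1e-12:
            truth.circular_median[daytype] = summaries.circular_median_time(curve)
        truth.amr[daytype] = summaries.amplitude_mean_ratio(curve)
    truth.amr_contrast = summaries.amr_contrast_from_curves(
        summaries.DiurnalCurve("weekday", truth.grid, truth.weekday_curve),
        summaries.DiurnalCurve("weekend", truth.grid, truth.weekend_curve),
    )


def simulate_series(spec: SyntheticSpec,
                    term: str = "synthetic",
                    location: str = "SIM") -> tuple[HourlySeries, GroundTruth]:
    """Simulate one annotated hourly series plus its ground-truth record.

    The series starts at 00:00 on ``spec.start`` (2018-01-01, a Monday, by
    default) on an hourly grid in zone UTC, so clock hour equals grid hour and
    weekday/weekend structure follows the real 2018 calendar. The observed
    value at hour x is

        clip_0[ baseline + trend(x/24) + daytype harmonics(t(x))
                + surges(x) + Gaussian noise ]

    optionally followed by per-week rescaling to max 100.
    """
    from . import summaries  # minute grid convention lives there

    rng = np.random.default_rng(spec.seed)
    n = spec.n_hours
    shell = _annotated_shell(spec.start, n).with_rsv(np.zeros(n))
    shell = replace(shell, term=term, location=location)
    ann = shell.frame

    t = ann["hour_of_day"].to_numpy(dtype=float)
    is_we = ann["is_weekend"].to_numpy(dtype=bool)
    days = ann["elapsed_days"].to_numpy(dtype=float)
    x = ann["elapsed_hours"].to_numpy(dtype=np.int64)

    mean = spec.baseline + spec.trend(days)
    mean = mean + np.where(is_we, spec.weekend_level, 0.0)
    for h in spec.weekday_harmonics:
        mean = mean + np.where(~is_we, h.amplitude * np.cos(h.n * OMEGA * t - h.phase), 0.0)
    for h in spec.weekend_harmonics:
        mean = mean + np.where(is_we, h.amplitude * np.cos(h.n * OMEGA * t - h.phase), 0.0)

    surge = np.zeros(n)
    for s in spec.outliers:
        surge += np.where((x >= s.start_hour) & (x < s.start_hour + s.duration_hours),
                          s.magnitude, 0.0)

    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    values = np.clip(mean + surge + noise, 0.0, None)

    series = shell.with_rsv(values)
    if spec.per_week_rescale:
        series = apply_weekly_rescale(series)

    grid = summaries.minute_grid()
    mid_day = 0.5 * (float(days.min()) + float(days.max()))  # study midpoint
    truth = GroundTruth(
        spec=spec,
        mean_curve=mean,
        outlier_signal=surge,
        weekday_curve=spec.daytype_curve("weekday", grid, mid_day),
        weekend_curve=spec.daytype_curve("weekend", grid, mid_day),
        grid=grid,
    )
    for daytype, harmonics in (("weekday", spec.weekday_harmonics),
                               ("weekend", spec.weekend_harmonics)):
        for h in harmonics:
            truth.harmonic_coefs[(daytype, h.n, "cos")] = h.cos_coef
            truth.harmonic_coefs[(daytype, h.n, "sin")] = h.sin_coef
    _true_summaries(truth)
    return series, truth


MEAN_SIM = -1  # simulated series carry the averaged-series sentinel


def apply_weekly_rescale(series: HourlySeries, integerize: bool = False) -> HourlySeries:
    """Rescale each consecutive 168-hour window to a maximum of 100.

    Emulates Trends' independent scaling of each weekly request window. An
    all-zero week is left all-zero. With ``integerize`` the rescaled values
    are rounded to integers like raw Trends output.
    """
    values = series.rsv.copy()
    n = len(values)
    for start in range(0, n, WEEK_HOURS):
        chunk = values[start:start + WEEK_HOURS]
        peak = chunk.max()
        if peak > 0:
            chunk *= 100.0 / peak
        values[start:start + WEEK_HOURS] = chunk
    if integerize:
        values = np.round(values)
    return series.with_rsv(values)
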