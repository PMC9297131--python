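"""Block-bootstrap uncertainty for the diurnal summaries.

A residual-based circular moving-block bootstrap: blocks of fixed width
(default 20 hours, long enough to span the short-range serial dependence of
hourly search volume while short relative to the 24-hour cycle) are drawn
with replacement from the model residuals, wrapping at the series end, and
added back to the outlier-free fitted values.  Resampling residuals rather
than the raw series preserves the deterministic design (the weekday/weekend
pattern and the trend), which whole-series block resampling would scramble.

Each replicate is refitted by OLS with the nuisance support held fixed at the
original LASSO selection (re-selection per replicate is unstable and orders
of magnitude more costly; the summaries of interest depend on the harmonic
block).  From the replicate coefficient draws we report:

* percentile confidence intervals for the amplitude-to-mean ratios and the
  weekend-weekday contrast;
* arc-based percentile intervals for circular median times (percentiles of
  the signed shorter-arc deviations from the point estimate, mapped back to
  the clock);
* a per-day-type diurnality P value: a Wald statistic on the eight harmonic
  coefficients using the bootstrap covariance, referred to its chi-square(8)
  limit.  This operationalizes "the coefficients measuring diurnality exclude
  zero"; the conventional significance rule is P < .001.

All randomness flows from ``(seed, rep)``; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import FittedModel
from .simulate import OMEGA
from . import summaries as S

__all__ = ["BootstrapConfig", "block_resample", "bootstrap_summaries"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the residual circular moving-block bootstrap."""

    block_hours: int = 20
    n_reps: int = 1000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.block_hours < 1:
            raise ValueError("block_hours must be >= 1")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


def _resample_indices(n: int, config: BootstrapConfig, rep: int) -> np.ndarray:
    """Row indices of one circular moving-block resample (length n)."""
    L = config.block_hours
    if n < L:
        raise ValueError(f"series of length {n} is shorter than one {L}-hour block")
    rng = np.random.default_rng((config.seed, rep))
    n_blocks = int(np.ceil(n / L))
    starts = rng.integers(0, n, size=n_blocks)
    idx = (starts[:, None] + np.arange(L)[None, :]) % n
    return idx.reshape(-1)[:n]


def block_resample(values: np.ndarray, config: BootstrapConfig, rep: int) -> np.ndarray:
    """Circular moving-block resample of a vector (typically model residuals).

    ``ceil(n / block_hours)`` block start positions are drawn uniformly,
    blocks wrap at the series end, and the concatenation is truncated to the
    original length.  Identical (config.seed, rep) gives an identical
    resample.
    """
    values = np.asarray(values, dtype=float)
    return values[_resample_indices(len(values), config, rep)]


def _daytype_grid_basis(minutes: int = S.GRID_MINUTES) -> np.ndarray:
    """Minute-grid trig design (grid x 8), column order sin1,cos1,...,sin4,cos4."""
    t = S.minute_grid(minutes)
    cols = []
    for n in (1, 2, 3, 4):
        cols.append(np.sin(n * OMEGA * t))
        cols.append(np.cos(n * OMEGA * t))
    return np.column_stack(cols)


def bootstrap_summaries(model: FittedModel, config: BootstrapConfig,
                        term: str = "term",
                        return_replicates: bool = False):
    """Diurnal summary with bootstrap CIs and P values for one fitted series.

    Refits are vectorized: all replicate responses are regressed at once
    through a precomputed pseudoinverse of the original design (unpenalized
    block + frozen nuisance support).
    """
    design = model.design
    n = design.n
    base = model.fitted - model.nuisance_contribution  # outlier-free fitted
    resid = model.residuals

    meta_index = {km: j for j, km in enumerate(design.nuisance_meta)}
    cols = [meta_index[km] for km in model.selected_columns]
    N_sel = design.nuisance[:, cols].toarray() if cols else np.empty((n, 0))
    X = np.column_stack([design.unpenalized, N_sel])
    pinv = np.linalg.pinv(X)

    B = config.n_reps
    idx = np.empty((B, n), dtype=np.int64)
    for rep in range(B):
        idx[rep] = _resample_indices(n, config, rep)
    Y = base[None, :] + resid[idx]            # (B, n)
    coefs = Y @ pinv.T                        # (B, p)

    d = design.elapsed_days
    mid = 0.5 * (float(d.min()) + float(d.max()))
    t_mid = design.trend_basis.transform(np.array([mid]))[0]      # (3,)
    trend_mid = coefs[:, 1:4] @ t_mid

    G = _daytype_grid_basis()
    grid = S.minute_grid()
    rep_stats: dict[str, np.ndarray] = {}
    amp, mean_level = {}, {}
    for daytype, off in (("weekday", 0), ("weekend", 8)):
        level = coefs[:, 0] + trend_mid
        if daytype == "weekend":
            level = level + coefs[:, 20]
        curves = G @ coefs[:, 4 + off:12 + off].T + level[None, :]  # (grid, B)
        amp[daytype] = curves.max(axis=0) - curves.min(axis=0)
        mean_level[daytype] = curves.mean(axis=0)
        rep_stats[f"amr_{daytype}"] = amp[daytype] / mean_level[daytype]
        rep_stats[f"median_{daytype}"] = S.circular_median_from_values(curves, grid)
    rep_stats["amr_contrast"] = ((amp["weekend"] - amp["weekday"])
                                 / (0.5 * (mean_level["weekend"] + mean_level["weekday"])))

    # point estimates from the original fit
    curves0 = {dt: S.diurnal_curve(model, dt) for dt in ("weekday", "weekend")}
    point_median = {dt: S.circular_median_time(curves0[dt]) for dt in curves0}
    point_amr = {dt: S.amplitude_mean_ratio(curves0[dt]) for dt in curves0}
    point_contrast = S.amr_contrast_from_curves(curves0["weekday"], curves0["weekend"])

    lo_q = 100 * (1 - config.ci_level) / 2
    hi_q = 100 - lo_q
    ci: dict[str, tuple[float, float]] = {}
    degenerate = all(np.ptp(v) == 0 for v in rep_stats.values())
    for key in ("amr_weekday", "amr_weekend", "amr_contrast"):
        vals = rep_stats[key]
        ci[key] = (float(np.percentile(vals, lo_q)), float(np.percentile(vals, hi_q)))
    for daytype in ("weekday", "weekend"):
        meds = rep_stats[f"median_{daytype}"]
        delta = (meds - point_median[daytype] + 12.0) % 24.0 - 12.0  # shorter arc
        lo, hi = np.percentile(delta, [lo_q, hi_q])
        ci[f"median_{daytype}"] = ((point_median[daytype] + float(lo)) % 24.0,
                                   (point_median[daytype] + float(hi)) % 24.0)

    p_value: dict[str, float] = {}
    for daytype, off in (("weekday", 0), ("weekend", 8)):
        draws = coefs[:, 4 + off:12 + off]
        b0 = model.harmonic_coeffs[off:off + 8]
        sigma = np.cov(draws, rowvar=False)
        if not np.all(np.isfinite(sigma)) or np.allclose(sigma, 0):
            p_value[f"diurnality_{daytype}"] = float("nan")
            continue
        try:
            stat = float(b0 @ np.linalg.solve(sigma, b0))
        except np.linalg.LinAlgError:
            stat = float(b0 @ np.linalg.pinv(sigma) @ b0)
        p_value[f"diurnality_{daytype}"] = float(stats.chi2.sf(stat, df=8))
        p_value[f"wald_{daytype}"] = stat

    if degenerate:
        for key in list(ci):
            if key.startswith("amr"):
                pt = {"amr_weekday": point_amr["weekday"],
                      "amr_weekend": point_amr["weekend"],
                      "amr_contrast": point_contrast}[key]
            else:
                pt = point_median[key.removeprefix("median_")]
            ci[key] = (pt, pt)

    summary = S.DiurnalSummary(
        term=term,
        circular_median=point_median,
        amr=point_amr,
        amr_contrast=point_contrast,
        median_diff_band=S.median_diff_band(point_median["weekday"],
                                            point_median["weekend"]),
        ci=ci,
        p_value=p_value,
        n_boot=B,
        degenerate=degenerate,
    )
    if return_replicates:
        return summary, pd.DataFrame(rep_stats)
    return summary
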