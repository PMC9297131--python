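"""End-to-end analysis runs: load/simulate, fit, bootstrap, tabulate, plot.

A :class:`RunConfig` (constructable from a YAML file) fully determines a run:
input source (CSV path or synthetic scenario), term list, time-zone map,
nuisance width preset, CV settings, bootstrap settings, significance
threshold, and output directory.  One base seed fans out deterministically to
the simulator, the cross-validation bookkeeping, and the bootstrap, so a
manifest (written as JSON next to the outputs) reproduces every table
byte-for-byte.

Terms are analyzed independently (each term is a separate regression) and no
multiplicity correction is applied beyond the fixed significance threshold
(default P < .001).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .basis import WIDTH_PRESETS
from .bootstrap import BootstrapConfig, bootstrap_summaries
from .io import (HourlySeries, average_replicates, combine_locations,
                 read_series, to_local_time)
from .model import DiurnalHarmonicRegression
from .simulate import SyntheticSpec, simulate_series
from .summaries import circular_difference
from .viz import make_panel, render_polar

__all__ = ["RunConfig", "run_analysis", "run_sensitivity", "prepare_series"]

logger = logging.getLogger("diurnality")


@dataclass
class RunConfig:
    """All knobs of one analysis run."""

    terms: Sequence[str]
    output_dir: str | Path
    input_csv: str | Path | None = None          # exclusive with synthetic
    synthetic: Mapping | None = None             # kwargs for SyntheticSpec
    timezone_map: Mapping[str, str] = field(default_factory=dict)
    widths: str = "default"
    cv_folds: int = 10
    penalty_rule: str = "1se"
    block_hours: int = 20
    n_boot: int = 1000
    ci_level: float = 0.95
    significance: float = 0.001
    seed: int = 0
    figures: Sequence[str] = ("overall",)
    detrend_plots: bool = True

    def __post_init__(self) -> None:
        if not list(self.terms):
            raise ValueError("term list must not be empty")
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance threshold must lie in (0, 1)")
        if self.input_csv is None and self.synthetic is None:
            raise ValueError("configure either input_csv or a synthetic scenario")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ValueError(f"input CSV {self.input_csv} does not exist")
        if isinstance(self.widths, str) and self.widths not in WIDTH_PRESETS:
            raise ValueError(f"unknown width preset {self.widths!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def derived_seed(self, purpose: str, index: int = 0) -> int:
        """Deterministic per-purpose seed below 2**31 from the base seed."""
        stream = {"simulate": 1, "cv": 2, "bootstrap": 3}[purpose]
        ss = np.random.SeedSequence([int(self.seed), stream, int(index)])
        return int(ss.generate_state(1)[0] % (2**31))


def prepare_series(config: RunConfig, term: str, term_index: int = 0
                   ) -> HourlySeries:
    """Produce the one combined, annotated analysis series for a term.

    CSV input: read all (location, replicate) traces for the term, average
    replicates within each location, annotate each location in its configured
    zone, and pool locations on the local-clock grid.  Synthetic input: run
    the generator with a per-term derived seed.
    """
    if config.synthetic is not None:
        kwargs = dict(config.synthetic)
        kwargs.setdefault("seed", config.derived_seed("simulate", term_index))
        spec = SyntheticSpec(**kwargs)
        series, _ = simulate_series(spec, term=term)
        return series
    all_series = [s for s in read_series(config.input_csv) if s.term == term]
    if not all_series:
        raise ValueError(f"no rows for term {term!r} in {config.input_csv}")
    by_location: dict[str, list[HourlySeries]] = {}
    for s in all_series:
        by_location.setdefault(s.location, []).append(s)
    annotated = []
    for location, reps in sorted(by_location.items()):
        zone = config.timezone_map.get(location)
        if zone is None:
            raise ValueError(f"no time zone configured for location {location!r}")
        merged = average_replicates(reps)
        annotated.append(to_local_time(merged, zone))
    return combine_locations(annotated)


def _plot_input(series: HourlySeries, est: DiurnalHarmonicRegression,
                detrend: bool) -> HourlySeries:
    """Filtered (optionally also detrended, mean-restored) series for plots."""
    values = est.filtered_series_.copy()
    if detrend:
        m = est.model_
        trend_part = m.design.trend @ m.trend_coeffs
        values = values - trend_part + float(np.mean(trend_part))
    return series.with_rsv(np.clip(values, 0.0, None))


def run_analysis(config: RunConfig) -> pd.DataFrame:
    """Run the full pipeline for every term; write table, figures, manifest.

    Returns the summary table (one row per term, the machine twin of the
    headline characteristics table: circular medians with CIs, 2-hour
    difference band, AMRs with CIs, AMR contrast with CI, diurnality P
    values, and a significance flag at the configured threshold).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, stage_log = [], []
    for i, term in enumerate(config.terms):
        t0 = time.perf_counter()
        series = prepare_series(config, term, i)
        stage_log.append({"term": term, "stage": "prepare",
                          "rows": len(series), "seconds": round(time.perf_counter() - t0, 3)})
        t0 = time.perf_counter()
        est = DiurnalHarmonicRegression(
            widths=config.widths, cv_folds=config.cv_folds,
            penalty_rule=config.penalty_rule,
            seed=config.derived_seed("cv", i))
        est.fit(series)
        stage_log.append({"term": term, "stage": "fit",
                          "rows": len(series.rsv),
                          "selected": len(est.selected_columns_),
                          "seconds": round(time.perf_counter() - t0, 3)})
        t0 = time.perf_counter()
        boot = BootstrapConfig(block_hours=config.block_hours,
                               n_reps=config.n_boot,
                               seed=config.derived_seed("bootstrap", i),
                               ci_level=config.ci_level)
        summary = bootstrap_summaries(est.model_, boot, term=term)
        stage_log.append({"term": term, "stage": "bootstrap",
                          "rows": config.n_boot,
                          "seconds": round(time.perf_counter() - t0, 3)})
        row = summary.to_row()
        for daytype in ("weekday", "weekend"):
            p = summary.p_value.get(f"diurnality_{daytype}", float("nan"))
            row[f"significant_{daytype}"] = bool(np.isfinite(p) and p < config.significance)
        rows.append(row)

        for grouping in config.figures:
            panel = make_panel(_plot_input(series, est, config.detrend_plots),
                               grouping, term=term)
            render_polar(panel, out_dir / f"{term}_{grouping}.png")

    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "summary.csv", index=False)
    manifest = {
        "package_version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else
                       dict(v) if isinstance(v, Mapping) else
                       list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "derived_seeds": {
            f"{purpose}[{i}]": config.derived_seed(purpose, i)
            for purpose in ("simulate", "cv", "bootstrap")
            for i in range(len(list(config.terms)))},
        "stages": stage_log,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for entry in stage_log:
        logger.info("%(term)s %(stage)s: %(rows)s rows in %(seconds)ss", entry)
    return table


def run_sensitivity(config: RunConfig,
                    presets: Sequence[str] = ("default", "sensitivity_a",
                                              "sensitivity_b")) -> pd.DataFrame:
    """Re-run the fit under several nuisance width ladders and compare.

    Returns one row per (term, preset pair) with the circular-median
    differences (minutes, shorter arc) and AMR differences between presets.
    The bootstrap is skipped: the comparison concerns the point summaries.
    """
    presets = list(presets)
    if len(presets) < 2:
        raise ValueError("sensitivity analysis needs at least two width presets")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_preset: dict[str, dict[str, dict]] = {}
    for i, term in enumerate(config.terms):
        series = prepare_series(config, term, i)
        for preset in presets:
            est = DiurnalHarmonicRegression(
                widths=preset, cv_folds=config.cv_folds,
                penalty_rule=config.penalty_rule,
                seed=config.derived_seed("cv", i))
            est.fit(series)
            from . import summaries as S
            m = est.model_
            rec = {}
            for daytype in ("weekday", "weekend"):
                curve = S.diurnal_curve(m, daytype)
                rec[f"median_{daytype}"] = S.circular_median_time(curve)
                rec[f"amr_{daytype}"] = S.amplitude_mean_ratio(curve)
            per_preset.setdefault(term, {})[preset] = rec
    rows = []
    for term, by_preset in per_preset.items():
        for a_i in range(len(presets)):
            for b_i in range(a_i + 1, len(presets)):
                a, b = presets[a_i], presets[b_i]
                ra, rb = by_preset[a], by_preset[b]
                row = {"term": term, "preset_a": a, "preset_b": b}
                for daytype in ("weekday", "weekend"):
                    row[f"median_diff_min_{daytype}"] = abs(circular_difference(
                        ra[f"median_{daytype}"], rb[f"median_{daytype}"])) * 60.0
                    row[f"amr_diff_{daytype}"] = abs(
                        ra[f"amr_{daytype}"] - rb[f"amr_{daytype}"])
                rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "sensitivity.csv", index=False)
    return table
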