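"""Normalized 24-hour polar plots of hourly search patterns.

Three figure families: the overall mean daily profile, one profile per day of
week, and per-season profiles split weekday (solid) vs weekend (dashed).
Each group's 24 hourly means are normalized by the minimum hour so the
quietest hour sits at radius 1.0; midnight is at the top and hours run
clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .io import HourlySeries
from .summaries import polar_normalize

__all__ = ["PolarPanel", "hourly_means", "make_panel", "render_polar"]

GROUPINGS = ("overall", "day_of_week", "season_daytype")

_DOW = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
_SEASON_COLORS = {"winter": "tab:blue", "spring": "tab:green",
                  "summer": "tab:orange", "fall": "tab:red"}


@dataclass
class PolarPanel:
    """Data behind one polar figure: per-group normalized 24-hour profiles."""

    term: str
    grouping: str
    series: dict[str, np.ndarray]           # group label -> 24 values, min 1.0
    missing: list[str] = field(default_factory=list)


def hourly_means(series: HourlySeries | pd.DataFrame,
                 grouping: str = "overall") -> dict[str, np.ndarray]:
    """Mean RSV by local hour within each group of the requested grouping.

    Groupings: ``overall`` (one 24-vector), ``day_of_week`` (seven), and
    ``season_daytype`` (season x weekday/weekend). Groups with no observed
    hours are reported via NaN vectors (flagged missing panels).
    """
    frame = series.frame if isinstance(series, HourlySeries) else series
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    needed = {"rsv", "hour_of_day", "day_of_week", "season", "is_weekend"}
    if not needed.issubset(frame.columns):
        raise ValueError("series must carry local-time annotations")

    def by_hour(sub: pd.DataFrame) -> np.ndarray:
        means = sub.groupby("hour_of_day")["rsv"].mean()
        return means.reindex(range(24)).to_numpy(dtype=float)

    if grouping == "overall":
        return {"overall": by_hour(frame)}
    if grouping == "day_of_week":
        return {_DOW[d]: by_hour(frame[frame["day_of_week"] == d])
                for d in range(7)}
    out = {}
    for season in ("winter", "spring", "summer", "fall"):
        for daytype, mask in (("weekday", ~frame["is_weekend"]),
                              ("weekend", frame["is_weekend"])):
            sub = frame[(frame["season"] == season) & mask]
            out[f"{season}_{daytype}"] = by_hour(sub)
    return out


def make_panel(series: HourlySeries | pd.DataFrame, grouping: str,
               term: str | None = None) -> PolarPanel:
    """Group, average, and min-normalize a filtered series into a panel."""
    if term is None:
        term = series.term if isinstance(series, HourlySeries) else "term"
    raw = hourly_means(series, grouping)
    normalized, missing = {}, []
    for label, values in raw.items():
        if np.any(~np.isfinite(values)):
            missing.append(label)
            continue
        normalized[label] = polar_normalize(values)
    return PolarPanel(term=term, grouping=grouping, series=normalized,
                      missing=missing)


def _style(label: str) -> dict:
    parts = label.split("_")
    style: dict = {"linewidth": 1.4}
    if parts[-1] == "weekend":
        style["linestyle"] = "--"
    elif parts[-1] == "weekday":
        style["linestyle"] = "-"
    if parts[0] in _SEASON_COLORS:
        style["color"] = _SEASON_COLORS[parts[0]]
    return style


def _draw(panel: PolarPanel, title: str | None = None):
    """Draw the polar axes for a panel; returns (fig, ax)."""
    theta = np.arange(24) * (2 * np.pi / 24)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_offset(np.pi / 2)   # 00:00 at the top
    ax.set_theta_direction(-1)       # clockwise
    for label, values in panel.series.items():
        closed_t = np.append(theta, theta[0])
        closed_v = np.append(values, values[0])
        ax.plot(closed_t, closed_v, label=label, **_style(label))
    ax.set_xticks(theta[::3])
    ax.set_xticklabels([f"{h:02d}" for h in range(0, 24, 3)])
    ax.set_title(title or f"{panel.term} ({panel.grouping})")
    if len(panel.series) > 1:
        ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=7)
    return fig, ax


def render_polar(panel: PolarPanel, path, title: str | None = None) -> None:
    """Write one polar figure: midnight at top, hours clockwise, radius >= 1."""
    fig, _ = _draw(panel, title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
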