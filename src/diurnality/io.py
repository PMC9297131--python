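"""Hourly relative-search-volume (RSV) series: container, CSV I/O, time handling.

The canonical in-memory object is :class:`HourlySeries`: one search term at one
location (e.g. a US state) for one download replicate, with a strictly hourly
:class:`pandas.DatetimeIndex` and an ``rsv`` column in [0, 100] for raw series.
Google Trends returns each week of hourly data scaled independently to a 0-100
"relative search volume"; downstream analysis works on replicate-averaged,
location-combined series, which are real-valued and may exceed no bound other
than nonnegativity.

Local-time annotations (hour of day, day of week, weekend flag, meteorological
season, elapsed hours/days since local midnight on Jan 1 of the study year) are
attached by :func:`to_local_time` and are what the regression bases consume.
"""

from __future__ import annotations

import zoneinfo
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HourlySeries",
    "SchemaError",
    "ValidationError",
    "MEAN_REPLICATE",
    "read_series",
    "write_series",
    "to_local_time",
    "average_replicates",
    "combine_locations",
    "season_of_month",
]

#: Sentinel replicate id for replicate-averaged series.
MEAN_REPLICATE = -1

#: Location label for multi-state combined series.
COMBINED_LOCATION = "combined"

_DEFAULT_SCHEMA = {
    "term": "term",
    "location": "location",
    "timestamp": "timestamp_utc",
    "replicate": "replicate",
    "rsv": "rsv",
}

ANNOTATION_COLUMNS = (
    "hour_of_day",
    "day_of_week",
    "is_weekend",
    "season",
    "elapsed_hours",
    "elapsed_days",
)


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


class ValidationError(ValueError):
    """Series content violates an invariant (ordering, range, alignment)."""


def season_of_month(month: int) -> str:
    """Meteorological season (DJF/MAM/JJA/SON) of a calendar month."""
    if month in (12, 1, 2):
        return "winter"
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    return "fall"


@dataclass
class HourlySeries:
    """One hourly RSV trace for a (term, location, replicate) triple.

    Parameters
    ----------
    term : str
        Free-text search term.
    location : str
        Region code (e.g. a US state abbreviation) or ``"combined"``.
    replicate : int
        Download replicate id; ``MEAN_REPLICATE`` (-1) after averaging.
    frame : pandas.DataFrame
        Indexed by a strictly increasing hourly DatetimeIndex (UTC-aware for
        raw series, naive local-clock for combined series) with an ``rsv``
        column plus any local-time annotation columns.
    zone : str or None
        IANA zone used for local annotations; ``"local"`` for series already
        on a local-clock (naive) index.
    allow_gaps : bool
        Whether missing hours are tolerated (they are merely flagged; the
        regression runs on observed rows only).
    is_raw : bool
        Raw (unaveraged, uncombined) series must satisfy rsv <= 100.
    """

    term: str
    location: str
    replicate: int
    frame: pd.DataFrame
    zone: str | None = None
    allow_gaps: bool = False
    is_raw: bool = True

    def __post_init__(self) -> None:
        self._validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def rsv(self) -> np.ndarray:
        return self.frame["rsv"].to_numpy(dtype=float)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def annotated(self) -> bool:
        return all(c in self.frame.columns for c in ANNOTATION_COLUMNS)

    @property
    def has_gaps(self) -> bool:
        if len(self.frame) < 2:
            return False
        steps = np.diff(self.frame.index.asi8) / 3.6e12
        return bool(np.any(steps != 1.0))

    def with_rsv(self, values: np.ndarray, **changes) -> "HourlySeries":
        """Copy of this series with replaced RSV values (and field changes)."""
        frame = self.frame.copy()
        frame["rsv"] = np.asarray(values, dtype=float)
        return replace(self, frame=frame, **changes)

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        if "rsv" not in self.frame.columns:
            raise SchemaError("frame must have an 'rsv' column")
        if len(self.frame) == 0:
            raise ValidationError(f"empty series for term={self.term!r}")
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValidationError("index must be a DatetimeIndex")
        steps = np.diff(idx.asi8) / 3.6e12  # hours
        if len(steps) and np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0)) + 1
            raise ValidationError(
                f"timestamps not strictly increasing at row {bad} "
                f"(term={self.term!r}, location={self.location!r})"
            )
        if len(steps) and np.any(steps != 1.0):
            if not self.allow_gaps:
                bad = int(np.argmax(steps != 1.0)) + 1
                raise ValidationError(
                    f"non-hourly step at row {bad}: gaps must be explicitly allowed"
                )
            if np.any(steps != np.round(steps)):
                raise ValidationError("gap sizes must be whole hours")
        rsv = self.frame["rsv"].to_numpy(dtype=float)
        if not np.all(np.isfinite(rsv)):
            bad = int(np.argmax(~np.isfinite(rsv)))
            raise ValidationError(f"non-finite rsv at row {bad}")
        if np.any(rsv < 0):
            bad = int(np.argmax(rsv < 0))
            raise ValidationError(f"negative rsv at row {bad} (value {rsv[bad]})")
        if self.is_raw and np.any(rsv > 100):
            bad = int(np.argmax(rsv > 100))
            raise ValidationError(f"raw rsv exceeds 100 at row {bad} (value {rsv[bad]})")


# ---------------------------------------------------------------------------
# CSV I/O (long format: term, location, timestamp_utc, replicate, rsv)
# ---------------------------------------------------------------------------

def read_series(path, schema: Mapping[str, str] | None = None,
                allow_gaps: bool = False) -> list[HourlySeries]:
    """Read a long-format CSV into one :class:`HourlySeries` per (term, location, replicate).

    ``schema`` maps the logical names {term, location, timestamp, replicate, rsv}
    to the file's column names. Parse errors are reported with 1-based data row
    numbers.
    """
    schema = dict(_DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    df = df.rename(columns={v: k for k, v in schema.items()})

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    if ts.isna().any():
        rows = (np.flatnonzero(ts.isna()) + 1).tolist()[:5]
        raise ValidationError(f"unparseable timestamps at data row(s) {rows} in {path}")
    rsv = pd.to_numeric(df["rsv"], errors="coerce")
    if rsv.isna().any():
        rows = (np.flatnonzero(rsv.isna()) + 1).tolist()[:5]
        raise ValidationError(f"non-numeric rsv at data row(s) {rows} in {path}")
    df = df.assign(timestamp=ts, rsv=rsv)

    out: list[HourlySeries] = []
    for (term, loc, rep), grp in df.groupby(["term", "location", "replicate"], sort=True):
        frame = pd.DataFrame({"rsv": grp["rsv"].to_numpy(dtype=float)},
                             index=pd.DatetimeIndex(grp["timestamp"], name="timestamp_utc"))
        rep_i = int(rep)
        out.append(HourlySeries(term=str(term), location=str(loc), replicate=rep_i,
                                frame=frame, allow_gaps=allow_gaps,
                                is_raw=(rep_i != MEAN_REPLICATE)))
    return out


def write_series(series_list: Iterable[HourlySeries] | HourlySeries, path) -> None:
    """Write series to the long CSV format (inverse of :func:`read_series`)."""
    if isinstance(series_list, HourlySeries):
        series_list = [series_list]
    parts = []
    for s in series_list:
        idx = s.frame.index
        if idx.tz is None:
            # naive local-clock index: serialize as-is (read back as UTC-naive)
            stamps = idx.strftime("%Y-%m-%dT%H:%M:%S")
        else:
            stamps = idx.tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%SZ")
        parts.append(pd.DataFrame({
            "term": s.term,
            "location": s.location,
            "timestamp_utc": stamps,
            "replicate": s.replicate,
            "rsv": s.frame["rsv"].to_numpy(dtype=float),
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Local-time annotation
# ---------------------------------------------------------------------------

def _annotate(frame: pd.DataFrame, local: pd.DatetimeIndex,
              anchor: pd.Timestamp, utc_index: pd.DatetimeIndex) -> pd.DataFrame:
    """Attach annotation columns derived from local clock times.

    ``anchor`` is local midnight on Jan 1 of the study year expressed on the
    same scale as ``utc_index`` (so elapsed hours advance 1 per hourly row even
    across DST shifts).
    """
    frame = frame.copy()
    frame["hour_of_day"] = local.hour
    frame["day_of_week"] = local.dayofweek  # Monday=0 .. Sunday=6
    frame["is_weekend"] = local.dayofweek >= 5
    frame["season"] = [season_of_month(m) for m in local.month]
    elapsed = (utc_index.asi8 - anchor.value) / 3.6e12
    if np.any(np.abs(elapsed - np.round(elapsed)) > 1e-9):
        raise ValidationError("timestamps are not on a whole-hour grid")
    frame["elapsed_hours"] = np.round(elapsed).astype(np.int64)
    frame["elapsed_days"] = frame["elapsed_hours"] / 24.0
    return frame


def to_local_time(series: HourlySeries, zone: str) -> HourlySeries:
    """Annotate a UTC series with local-time covariates for ``zone``.

    Annotation is a pure function of (UTC timestamp, zone): re-annotation is
    idempotent. DST transitions are kept as-is (the local clock jumps; the
    hourly UTC grid does not).
    """
    try:
        zoneinfo.ZoneInfo(zone)
    except (zoneinfo.ZoneInfoNotFoundError, ValueError) as exc:
        raise ValueError(f"unknown IANA time zone {zone!r}") from exc
    idx = series.frame.index
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    else:
        idx = idx.tz_convert("UTC")
    local = idx.tz_convert(zone)
    year = int(local[0].year)
    anchor = pd.Timestamp(year=year, month=1, day=1, tz=zone).tz_convert("UTC")
    frame = series.frame.copy()
    frame.index = idx
    frame = _annotate(frame, local, anchor, idx)
    return replace(series, frame=frame, zone=zone)


def _annotate_naive_local(frame: pd.DataFrame) -> pd.DataFrame:
    """Annotate a series whose index is already naive local-clock time."""
    idx = frame.index
    year = int(idx[0].year)
    anchor = pd.Timestamp(year=year, month=1, day=1)
    return _annotate(frame, idx, anchor, idx)


# ---------------------------------------------------------------------------
# Replicate averaging and location pooling
# ---------------------------------------------------------------------------

def average_replicates(series_list: Sequence[HourlySeries]) -> HourlySeries:
    """Pointwise mean RSV across replicate downloads of one term-location pair.

    All replicates must share the exact timestamp grid; the result carries the
    ``MEAN_REPLICATE`` sentinel and is no longer bound by the raw <=100 cap
    (means of integers stay <=100 anyway, but the flag marks provenance).
    """
    if not series_list:
        raise ValidationError("no replicates supplied")
    first = series_list[0]
    for s in series_list[1:]:
        if (s.term, s.location) != (first.term, first.location):
            raise ValidationError("replicates must share term and location")
        if len(s) != len(first) or not s.frame.index.equals(first.frame.index):
            raise ValidationError(
                f"replicate timestamp grids differ for term={first.term!r}, "
                f"location={first.location!r}"
            )
    mean = np.mean([s.rsv for s in series_list], axis=0)
    frame = pd.DataFrame({"rsv": mean}, index=first.frame.index.copy())
    out = HourlySeries(term=first.term, location=first.location,
                       replicate=MEAN_REPLICATE, frame=frame,
                       allow_gaps=first.allow_gaps, is_raw=False)
    if first.zone is not None and first.zone != "local":
        out = to_local_time(out, first.zone)
    return out


def combine_locations(series_list: Sequence[HourlySeries],
                      method: str = "mean") -> HourlySeries:
    """Pool locally-annotated series from several locations into one series.

    The pooled series is indexed by the *local clock* timestamp; the value at
    each local hour is the mean RSV over the locations observed at that local
    hour. (Each state's 6 AM is aligned with every other state's 6 AM, which is
    what makes pooled diurnal harmonics meaningful.) DST artifacts — the
    skipped spring hour and the doubled fall hour — are kept: the doubled hour
    is averaged, the skipped hour is a flagged gap.
    """
    if method != "mean":
        raise ValueError(f"unsupported combine method {method!r}")
    if not series_list:
        raise ValidationError("no series to combine")
    term = series_list[0].term
    parts = []
    for s in series_list:
        if s.term != term:
            raise ValidationError("all series must share the search term")
        if not s.annotated or s.zone is None:
            raise ValidationError("series must be locally annotated before combining")
        idx = s.frame.index
        local = idx.tz_convert(s.zone).tz_localize(None) if idx.tz is not None else idx
        parts.append(pd.DataFrame({"rsv": s.rsv}, index=local))
    pooled = (pd.concat(parts).groupby(level=0)["rsv"].mean().sort_index())
    frame = pd.DataFrame({"rsv": pooled.to_numpy()},
                         index=pd.DatetimeIndex(pooled.index, name="local_time"))
    frame = _annotate_naive_local(frame)
    locs = sorted({s.location for s in series_list})
    location = locs[0] if len(locs) == 1 else COMBINED_LOCATION
    return HourlySeries(term=term, location=location, replicate=MEAN_REPLICATE,
                        frame=frame, zone="local", allow_gaps=True, is_raw=False)
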