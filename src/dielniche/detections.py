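"""Camera-trap detection tables and their collapse into independent events.

A camera trigger produces one or more photographs; the unit of analysis in
diel-activity work is the *independent event*: a run of photographs of the
same species at the same camera in which no two consecutive photographs are
separated by more than a threshold gap (30 minutes by default).  The event is
timestamped by its first photograph.

Events are labelled with a climatic season by calendar month: the default
split is warm = April–September, cold = October–March, matching the montane
monsoon study system the package ships demo data for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WARM = "warm"
COLD = "cold"

#: canonical column names used throughout the package
SITE, SPECIES, TIMESTAMP, LATITUDE, LONGITUDE, COUNT = (
    "site_id", "species", "timestamp", "latitude", "longitude", "count",
)
EVENT_TIME = "event_time"
SEASON = "season"


class DetectionReadError(ValueError):
    """Raised when a detection table cannot be read under the given schema."""


@dataclass(frozen=True)
class DetectionRecord:
    """One camera-trap photograph trigger."""

    site_id: str
    species: str
    timestamp: datetime
    latitude: float | None = None
    longitude: float | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.site_id or not self.species:
            raise ValueError("site_id and species must be non-empty")
        if self.count < 1:
            raise ValueError("count must be a positive integer")


@dataclass(frozen=True)
class SeasonConfig:
    """Calendar-month definition of the two climatic seasons.

    The two month sets must partition {1..12}.  Defaults follow the warm
    (Apr–Sep) / cold (Oct–Mar) split of a temperate monsoon climate.
    """

    warm_months: frozenset[int] = frozenset(range(4, 10))
    cold_months: frozenset[int] = frozenset({10, 11, 12, 1, 2, 3})

    def __post_init__(self) -> None:
        if self.warm_months & self.cold_months:
            raise ValueError("warm and cold month sets overlap")
        if self.warm_months | self.cold_months != frozenset(range(1, 13)):
            raise ValueError("warm and cold month sets must partition months 1..12")

    def season_of(self, month: int) -> str:
        return WARM if month in self.warm_months else COLD


@dataclass
class EventTable:
    """Independent events plus provenance of the collapse that produced them.

    ``events`` has columns (site_id, species, event_time[, season]); within any
    (site_id, species) group consecutive event times differ by strictly more
    than ``interval_minutes``.
    """

    events: pd.DataFrame
    interval_minutes: float = 30.0
    n_records_in: int = 0
    n_parse_failures: int = 0

    def __len__(self) -> int:
        return len(self.events)

    def to_csv(self, path) -> None:
        out = self.events.copy()
        out[EVENT_TIME] = out[EVENT_TIME].dt.strftime("%Y-%m-%dT%H:%M:%S")
        out.to_csv(path, index=False)


@dataclass
class ParseFailure:
    row: int
    message: str


def records_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    rows = [
        (r.site_id, r.species, r.timestamp, r.latitude, r.longitude, r.count)
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=[SITE, SPECIES, TIMESTAMP, LATITUDE, LONGITUDE, COUNT]
    )


def read_detections(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    datetime_format: str = "%Y-%m-%d %H:%M:%S",
    max_failure_fraction: float = 0.1,
    sep: str = ",",
) -> tuple[pd.DataFrame, list[ParseFailure]]:
    """Read a delimited detection table into the canonical schema.

    Parameters
    ----------
    path
        CSV/TSV file with one row per photograph.
    schema
        Mapping from canonical names (``site_id``, ``species``, ``timestamp``
        and optionally ``latitude``, ``longitude``, ``count``) to the file's
        column names.  ``None`` means the file already uses canonical names.
    datetime_format
        ``strptime`` format of the timestamp column.
    max_failure_fraction
        Abort if more than this fraction of rows fail to parse.

    Returns
    -------
    (frame, failures)
        ``frame`` holds the successfully parsed rows in input order;
        ``failures`` lists 1-based data-row numbers with messages.
    """
    schema = dict(schema or {})
    for key in (SITE, SPECIES, TIMESTAMP):
        schema.setdefault(key, key)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except FileNotFoundError:
        raise DetectionReadError(f"detection file not found: {path}") from None
    missing = [c for c in (schema[SITE], schema[SPECIES], schema[TIMESTAMP])
               if c not in raw.columns]
    if missing:
        raise DetectionReadError(f"mapped columns missing from {path}: {missing}")

    if raw.empty:
        logger.warning("detection file %s contains a header but no rows", path)
        empty = pd.DataFrame(columns=[SITE, SPECIES, TIMESTAMP, LATITUDE, LONGITUDE, COUNT])
        empty[TIMESTAMP] = pd.to_datetime(empty[TIMESTAMP])
        return empty, []

    frame = pd.DataFrame({
        SITE: raw[schema[SITE]].astype(str),
        SPECIES: raw[schema[SPECIES]].astype(str),
    })
    parsed = pd.to_datetime(raw[schema[TIMESTAMP]], format=datetime_format,
                            errors="coerce")
    frame[TIMESTAMP] = parsed
    for opt, default in ((LATITUDE, np.nan), (LONGITUDE, np.nan), (COUNT, 1)):
        col = schema.get(opt, opt)
        if col in raw.columns:
            frame[opt] = pd.to_numeric(raw[col], errors="coerce")
        else:
            frame[opt] = default

    failures = [
        ParseFailure(row=i + 1, message=f"unparseable timestamp: {raw[schema[TIMESTAMP]].iat[i]!r}")
        for i in np.flatnonzero(parsed.isna().to_numpy())
    ]
    bad_label = (frame[SITE].str.len() == 0) | (frame[SPECIES].str.len() == 0)
    failures += [ParseFailure(row=i + 1, message="empty site_id or species")
                 for i in np.flatnonzero(bad_label.to_numpy() & parsed.notna().to_numpy())]
    if failures and len(failures) / len(raw) > max_failure_fraction:
        raise DetectionReadError(
            f"{len(failures)}/{len(raw)} rows failed to parse "
            f"(rows {[f.row for f in failures[:10]]}...)"
        )
    for f in failures:
        logger.warning("row %d: %s", f.row, f.message)
    ok = parsed.notna().to_numpy() & ~bad_label.to_numpy()
    return frame.loc[ok].reset_index(drop=True), failures


def filter_independent_events(
    records: pd.DataFrame | Sequence[DetectionRecord],
    interval_minutes: float = 30.0,
) -> EventTable:
    """Collapse photographs into independent events by the chain rule.

    Within each (site_id, species) group sorted by time, a photograph starts a
    new event iff it is the group's first or its gap to the *immediately
    preceding* photograph exceeds ``interval_minutes``; a gap exactly equal to
    the threshold stays within the event.  The event time is the first
    photograph's timestamp.
    """
    if interval_minutes <= 0:
        raise ValueError("interval_minutes must be positive")
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    if records.empty:
        events = pd.DataFrame(columns=[SITE, SPECIES, EVENT_TIME])
        events[EVENT_TIME] = pd.to_datetime(events[EVENT_TIME])
        return EventTable(events, interval_minutes, n_records_in=0)

    df = records.sort_values([SITE, SPECIES, TIMESTAMP], kind="mergesort")
    gap = df.groupby([SITE, SPECIES], sort=False)[TIMESTAMP].diff()
    new_event = gap.isna() | (gap > pd.Timedelta(minutes=interval_minutes))
    starts = df.loc[new_event, [SITE, SPECIES, TIMESTAMP]].rename(
        columns={TIMESTAMP: EVENT_TIME}
    )
    starts = starts.sort_values([SITE, SPECIES, EVENT_TIME]).reset_index(drop=True)
    return EventTable(starts, interval_minutes, n_records_in=len(records))


def assign_season(table: EventTable, config: SeasonConfig | None = None) -> EventTable:
    """Label every event with its season by the calendar month of its date."""
    config = config or SeasonConfig()
    events = table.events.copy()
    months = events[EVENT_TIME].dt.month
    events[SEASON] = np.where(months.isin(sorted(config.warm_months)), WARM, COLD)
    return EventTable(events, table.interval_minutes,
                      table.n_records_in, table.n_parse_failures)


@dataclass
class EventSummary:
    """Per-species and per-species-per-season event counts."""

    per_species: dict[str, int] = field(default_factory=dict)
    per_species_season: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_species.values())


def summarize_events(table: EventTable) -> EventSummary:
    """Count events per species and per species-season.

    The grand total equals the sum of per-species counts, and each species
    count equals the sum of its season counts when seasons are assigned.
    """
    events = table.events
    summary = EventSummary()
    if events.empty:
        return summary
    summary.per_species = events.groupby(SPECIES).size().to_dict()
    if SEASON in events.columns:
        summary.per_species_season = (
            events.groupby([SPECIES, SEASON]).size().to_dict()
        )
    return summary
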