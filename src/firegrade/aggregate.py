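"""Daily aggregation of fixed-cadence station records.

Stations sample every channel on a fixed cadence (10 min by default).  The
index equations consume daily quantities: maximum air temperature, minimum
relative humidity, total precipitation, maximum wind speed, mean humus-layer
soil moisture, and consecutive-day rain counters.  This module turns raw
records into :class:`DailySummary` rows and those into per-day fire
assessments.

Gap policy: short interruptions (at most ``max_gap`` minutes) are bridged by
linear interpolation of the continuous channels and by zeros for
precipitation; longer interruptions leave the slots missing and set the
day's ``gap_flag``.  Days below ``min_coverage`` of their expected record
count raise :class:`~firegrade.errors.LowCoverageError` carrying the partial
summary.  Within a day, ingestion is order-insensitive and duplicate
timestamps are dropped.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDayError, LowCoverageError, SequenceError, ValidationError
from .indices import DailyFireAssessment, IndexEquations

__all__ = [
    "SensorRecord",
    "DailySummary",
    "AggregationConfig",
    "summarize_day",
    "update_runs",
    "summarize_series",
    "assess_series",
    "read_sensor_csv",
    "write_sensor_csv",
    "summaries_to_frame",
    "frame_to_summaries",
    "assessments_to_frame",
]

# Sensor operating ranges used for ingest validation.
TEMP_RANGE = (-55.0, 80.0)

#: Canonical CSV header for raw sensor files (percent columns are converted
#: to fractions on read).
SENSOR_CSV_COLUMNS = [
    "timestamp", "station_id", "air_temp_c", "rh_pct", "wind_ms",
    "precip_mm", "vwc10_pct", "vwc40_pct",
]

# Internal column names.
_CHANNELS = ["air_temp", "rel_humidity", "wind_speed", "precip",
             "soil_vwc_10cm", "soil_vwc_40cm"]
_CONTINUOUS = ["air_temp", "rel_humidity", "wind_speed",
               "soil_vwc_10cm", "soil_vwc_40cm"]


@dataclass(frozen=True)
class SensorRecord:
    """One timestamped multi-sensor observation from one station."""

    timestamp: dt.datetime
    station_id: str
    air_temp: float          # °C
    rel_humidity: float      # fraction
    wind_speed: float        # m/s
    precip: float            # mm accumulated over the sampling interval
    soil_vwc_10cm: float     # fraction
    soil_vwc_40cm: float     # fraction

    def __post_init__(self):
        if not TEMP_RANGE[0] <= self.air_temp <= TEMP_RANGE[1]:
            raise ValidationError(f"air_temp {self.air_temp} outside sensor range")
        for name in ("rel_humidity", "soil_vwc_10cm", "soil_vwc_40cm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.precip < 0:
            raise ValidationError("precip must be non-negative")
        if self.wind_speed < 0:
            raise ValidationError("wind_speed must be non-negative")


@dataclass(frozen=True)
class DailySummary:
    """Daily aggregates feeding the index equations.

    ``dry_run`` / ``wet_run`` count consecutive days (ending today) below /
    at-or-above the rain-day threshold; they are unset (None) until
    :func:`update_runs` has been applied in calendar order.
    """

    date: dt.date
    t_max: float
    rh_min: float
    precip_total: float
    wind_max: float
    humus_vwc: float
    soil40_vwc: float
    n_records: int
    gap_flag: bool
    dry_run: int | None = None
    wet_run: int | None = None


@dataclass(frozen=True)
class AggregationConfig:
    """Knobs of the daily aggregation.

    cadence : minutes between records (default 10).
    rain_day_threshold : daily total (mm) at or above which a day counts as
        a rain day (default 0.1).
    max_gap : longest interruption (minutes) bridged by interpolation
        (default 30).
    min_coverage : minimum fraction of expected records per day (default 0.8).
    humus_statistic : daily statistic of the 10 cm soil channel used as the
        humus-layer moisture ("mean" or "min").
    """

    cadence: int = 10
    rain_day_threshold: float = 0.1
    max_gap: int = 30
    min_coverage: float = 0.8
    humus_statistic: str = "mean"

    def __post_init__(self):
        if self.cadence <= 0 or self.rain_day_threshold <= 0 or self.max_gap <= 0:
            raise ValidationError("cadence, rain_day_threshold and max_gap must be positive")
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValidationError("min_coverage must be in (0, 1]")
        if self.humus_statistic not in ("mean", "min"):
            raise ValidationError("humus_statistic must be 'mean' or 'min'")

    @property
    def records_per_day(self) -> int:
        return (24 * 60) // self.cadence


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = [
        {
            "timestamp": pd.Timestamp(r.timestamp),
            "station_id": r.station_id,
            "air_temp": r.air_temp,
            "rel_humidity": r.rel_humidity,
            "wind_speed": r.wind_speed,
            "precip": r.precip,
            "soil_vwc_10cm": r.soil_vwc_10cm,
            "soil_vwc_40cm": r.soil_vwc_40cm,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def summarize_day(records, config: AggregationConfig | None = None) -> DailySummary:
    """Aggregate one station-day of records into a :class:`DailySummary`.

    Records may arrive in any order and may contain duplicate timestamps;
    they are sorted and de-duplicated first.  Run counters are left unset.

    Raises
    ------
    EmptyDayError
        If no records are supplied.
    LowCoverageError
        If fewer than ``min_coverage`` of the expected records are present;
        the partial summary is attached to the exception.
    """
    config = config or AggregationConfig()
    df = _records_to_frame(records)
    if df.empty:
        raise EmptyDayError("no records for this day")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp").drop_duplicates("timestamp")
    stations = df["station_id"].unique()
    if len(stations) != 1:
        raise ValidationError(f"records span several stations: {sorted(stations)}")
    days = df["timestamp"].dt.normalize().unique()
    if len(days) != 1:
        raise ValidationError("records span several calendar days")
    day_start = pd.Timestamp(days[0])

    grid = pd.date_range(
        day_start, day_start + pd.Timedelta(days=1),
        freq=f"{config.cadence}min", inclusive="left",
    )
    on_grid = df.set_index("timestamp").reindex(grid)
    n_records = int(on_grid[_CHANNELS].notna().all(axis=1).sum())
    # if timestamps are off-grid, fall back to the raw count
    n_records = max(n_records, 0) or len(df)

    max_gap_slots = config.max_gap // config.cadence
    missing = on_grid["air_temp"].isna()
    # lengths of missing runs on the grid
    run_id = (missing != missing.shift()).cumsum()
    run_len = missing.groupby(run_id).transform("sum")
    short_gap = missing & (run_len <= max_gap_slots)
    long_gap = missing & (run_len > max_gap_slots)
    gap_flag = bool(long_gap.any())

    filled = on_grid.copy()
    interp = filled[_CONTINUOUS].interpolate(method="time", limit_area="inside")
    for col in _CONTINUOUS:
        filled.loc[short_gap, col] = interp.loc[short_gap, col]
    filled.loc[short_gap, "precip"] = 0.0

    humus = (
        filled["soil_vwc_10cm"].mean()
        if config.humus_statistic == "mean"
        else filled["soil_vwc_10cm"].min()
    )
    summary = DailySummary(
        date=day_start.date(),
        t_max=float(filled["air_temp"].max()),
        rh_min=float(filled["rel_humidity"].min()),
        precip_total=float(filled["precip"].sum()),
        wind_max=float(filled["wind_speed"].max()),
        humus_vwc=float(humus),
        soil40_vwc=float(filled["soil_vwc_40cm"].mean()),
        n_records=min(n_records, config.records_per_day),
        gap_flag=gap_flag,
    )
    if n_records < config.min_coverage * config.records_per_day:
        raise LowCoverageError(
            f"{summary.date}: {n_records}/{config.records_per_day} records "
            f"below min_coverage={config.min_coverage}",
            partial=summary,
        )
    return summary


def update_runs(
    previous: DailySummary | None,
    today: DailySummary,
    config: AggregationConfig | None = None,
) -> DailySummary:
    """Set today's dry/wet consecutive-day counters from yesterday's.

    A day is a rain day when its precipitation total reaches the rain-day
    threshold.  Exactly one of the two counters is positive on any day.
    """
    config = config or AggregationConfig()
    if previous is not None:
        if today.date - previous.date != dt.timedelta(days=1):
            raise SequenceError(
                f"{today.date} does not immediately follow {previous.date}"
            )
        if previous.dry_run is None or previous.wet_run is None:
            raise SequenceError("previous summary has unset run counters")
    if today.precip_total < config.rain_day_threshold:
        dry = (previous.dry_run if previous else 0) + 1
        wet = 0
    else:
        wet = (previous.wet_run if previous else 0) + 1
        dry = 0
    return replace(today, dry_run=dry, wet_run=wet)


def summarize_series(
    df: pd.DataFrame, config: AggregationConfig | None = None
) -> list[DailySummary]:
    """Aggregate a multi-day record frame into consecutive daily summaries.

    Low-coverage days are kept (their partial summaries are flagged); a
    wholly missing calendar day breaks the run counters, which restart on
    the next observed day.
    """
    config = config or AggregationConfig()
    if df.empty:
        return []
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    summaries: list[DailySummary] = []
    prev: DailySummary | None = None
    for day, day_df in df.groupby(df["timestamp"].dt.normalize(), sort=True):
        try:
            s = summarize_day(day_df, config)
        except LowCoverageError as exc:
            s = replace(exc.partial, gap_flag=True)
        if prev is not None and s.date - prev.date != dt.timedelta(days=1):
            prev = None  # a missing day restarts the counters
        s = update_runs(prev, s, config)
        summaries.append(s)
        prev = s
    return summaries


def assess_series(
    summaries: Sequence[DailySummary],
    equations: IndexEquations | None = None,
) -> list[DailyFireAssessment]:
    """Score consecutive daily summaries into fire-weather assessments.

    Days flagged for data gaps are still scored; the flag is carried into
    the assessment's ``quality_flag``.
    """
    equations = equations or IndexEquations.published()
    out = []
    for s in summaries:
        out.append(
            equations.assess(
                s.date,
                t_max=s.t_max,
                rh_min=s.rh_min,
                precip_mm=s.precip_total,
                wind_max=s.wind_max,
                humus_vwc=s.humus_vwc,
                dry_run=s.dry_run,
                wet_run=s.wet_run,
                quality_flag=s.gap_flag,
            )
        )
    return out


# -- CSV interchange --------------------------------------------------------

def read_sensor_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw sensor CSV; percent columns become fractions."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(SENSOR_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sensor CSV missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "timestamp": df["timestamp"],
            "station_id": df["station_id"].astype(str),
            "air_temp": df["air_temp_c"].astype(float),
            "rel_humidity": df["rh_pct"].astype(float) / 100.0,
            "wind_speed": df["wind_ms"].astype(float),
            "precip": df["precip_mm"].astype(float),
            "soil_vwc_10cm": df["vwc10_pct"].astype(float) / 100.0,
            "soil_vwc_40cm": df["vwc40_pct"].astype(float) / 100.0,
        }
    )
    return out


def write_sensor_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an internal record frame as a raw sensor CSV (fractions → %)."""
    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%d %H:%M:%S"),
            "station_id": df["station_id"],
            "air_temp_c": df["air_temp"].round(4),
            "rh_pct": (df["rel_humidity"] * 100.0).round(4),
            "wind_ms": df["wind_speed"].round(4),
            "precip_mm": df["precip"].round(4),
            "vwc10_pct": (df["soil_vwc_10cm"] * 100.0).round(4),
            "vwc40_pct": (df["soil_vwc_40cm"] * 100.0).round(4),
        }
    )
    out.to_csv(path, index=False)


def summaries_to_frame(summaries: Sequence[DailySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date": [s.date.isoformat() for s in summaries],
            "t_max": [s.t_max for s in summaries],
            "rh_min": [s.rh_min for s in summaries],
            "precip_total": [s.precip_total for s in summaries],
            "wind_max": [s.wind_max for s in summaries],
            "humus_vwc": [s.humus_vwc for s in summaries],
            "soil40_vwc": [s.soil40_vwc for s in summaries],
            "n_records": [s.n_records for s in summaries],
            "gap_flag": [s.gap_flag for s in summaries],
            "dry_run": [s.dry_run for s in summaries],
            "wet_run": [s.wet_run for s in summaries],
        }
    )


def frame_to_summaries(df: pd.DataFrame) -> list[DailySummary]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DailySummary(
                date=dt.date.fromisoformat(str(row.date)[:10]),
                t_max=float(row.t_max),
                rh_min=float(row.rh_min),
                precip_total=float(row.precip_total),
                wind_max=float(row.wind_max),
                humus_vwc=float(row.humus_vwc),
                soil40_vwc=float(row.soil40_vwc),
                n_records=int(row.n_records),
                gap_flag=bool(row.gap_flag),
                dry_run=None if pd.isna(row.dry_run) else int(row.dry_run),
                wet_run=None if pd.isna(row.wet_run) else int(row.wet_run),
            )
        )
    return out


def assessments_to_frame(assessments: Sequence[DailyFireAssessment]) -> pd.DataFrame:
    return pd.DataFrame([a.as_row() for a in assessments])
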