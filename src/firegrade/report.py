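"""Statement generation: daily, monthly and annual tabular summaries.

A statement row aggregates the daily summaries over one period (day, month
or year) and tallies the fire-weather grades awarded in that period.  CSV is
the canonical output; an Excel writer is available when openpyxl is
installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .aggregate import DailySummary, summaries_to_frame
from .errors import EmptyReportError, ValidationError
from .indices import DailyFireAssessment

__all__ = ["Statement", "build_statement", "write_statement"]

Period = Literal["daily", "monthly", "annual"]

_PERIOD_FMT = {"daily": "%Y-%m-%d", "monthly": "%Y-%m", "annual": "%Y"}


@dataclass(frozen=True)
class Statement:
    """Per-period aggregates plus fire-grade counts."""

    period: Period
    table: pd.DataFrame

    def __post_init__(self):
        grade_cols = [f"grade_{g}_days" for g in range(1, 6)]
        counts = self.table[grade_cols].to_numpy().sum(axis=1)
        if not (counts == self.table["n_days"].to_numpy()).all():
            raise ValidationError("grade counts must sum to scored days")


def build_statement(
    assessments: Sequence[DailyFireAssessment],
    summaries: Sequence[DailySummary],
    period: Period = "monthly",
) -> Statement:
    """Aggregate assessments and daily summaries into one statement."""
    if period not in _PERIOD_FMT:
        raise ValidationError(f"unknown period {period!r}")
    if not assessments or not summaries:
        raise EmptyReportError("cannot build a statement from empty input")

    sf = summaries_to_frame(summaries)
    af = pd.DataFrame([a.as_row() for a in assessments])
    df = sf.merge(af[["date", "total", "grade"]], on="date", how="inner")
    if df.empty:
        raise EmptyReportError("assessments and summaries share no dates")
    key = pd.to_datetime(df["date"]).dt.strftime(_PERIOD_FMT[period])

    rows = []
    for per, g in df.groupby(key, sort=True):
        row = {
            "period": per,
            "n_days": len(g),
            "t_max_mean": g["t_max"].mean(),
            "t_max_max": g["t_max"].max(),
            "rh_min_mean": g["rh_min"].mean(),
            "rh_min_min": g["rh_min"].min(),
            "precip_total_mm": g["precip_total"].sum(),
            "wind_max_ms": g["wind_max"].max(),
            "humus_vwc_mean": g["humus_vwc"].mean(),
            "fire_index_mean": g["total"].mean(),
            "fire_index_max": g["total"].max(),
        }
        for grade in range(1, 6):
            row[f"grade_{grade}_days"] = int((g["grade"] == grade).sum())
        rows.append(row)
    table = pd.DataFrame(rows).round(4)
    return Statement(period=period, table=table)


def write_statement(
    assessments: Sequence[DailyFireAssessment],
    summaries: Sequence[DailySummary],
    period: Period,
    path: str | Path,
) -> Statement:
    """Build a statement and write it (CSV, or Excel for ``.xlsx`` paths).

    Re-running on identical input produces a byte-identical CSV.
    """
    stmt = build_statement(assessments, summaries, period)
    path = Path(path)
    if path.suffix == ".xlsx":
        stmt.table.to_excel(path, index=False)
    else:
        stmt.table.to_csv(path, index=False)
    return stmt
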