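"""Daily fire-weather component indices, composite score and grade.

The composite fire-weather index is the sum of six components,

    Y = Y'_A + Y'_B + Y'_C + Y'_D + Y'_E1 + Y'_E2,

where A–D are logistic scorings of daily maximum air temperature (°C),
daily minimum relative humidity (fraction), daily precipitation amount (mm,
with a dry-spell bonus) and daily maximum wind speed (m/s); E1 is a
phenology (vegetation-cover) term set by calendar season; and E2 is a
litter-layer soil-moisture correction driven by the volumetric water content
of the humus layer.  The composite is binned into fire-danger grades I–V.

Published scoring-curve coefficients are available as
:data:`PUBLISHED_PARAMS`; alternatively the curves can be refitted from the
step-interval sample sets (see :mod:`firegrade.model`) and supplied here.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .errors import StateError, ValidationError
from .model import StepLogisticResults

__all__ = [
    "LogisticParams",
    "PUBLISHED_PARAMS",
    "PhenologyConfig",
    "DailyFireAssessment",
    "IndexEquations",
    "index_a",
    "index_b",
    "index_c",
    "index_d",
    "index_e1",
    "index_e2",
    "composite_and_grade",
    "classify_grade",
]


@dataclass(frozen=True)
class LogisticParams:
    """Coefficients of one scoring curve  Y' = k / (1 + exp(alpha + beta*x))."""

    alpha: float
    beta: float
    k: float

    def __call__(self, x: float) -> float:
        eta = self.alpha + self.beta * x
        if eta >= 0:
            e = math.exp(-eta)
            return self.k * e / (1.0 + e)
        return self.k / (1.0 + math.exp(eta))


#: Published scoring-curve coefficients for indices A–D (humidity as fraction).
PUBLISHED_PARAMS: dict[str, LogisticParams] = {
    "A": LogisticParams(3.6421, -0.2428, 20.0),
    "B": LogisticParams(-6.0701, 12.1403, 20.0),
    "C": LogisticParams(-2.5545, 0.8685, 10.0),
    "D": LogisticParams(2.2844, -0.2396, 40.0),
}

#: Precipitation amount (mm/day) above which the C index drops to its
#: rain-suppressed branch 5*(t-1).
HEAVY_RAIN_MM = 10.0
#: Cap on the C index.
C_MAX = 50.0
#: Humus-layer VWC breakpoints of the soil-moisture correction.
E2_DRY_VWC = 0.05
E2_WET_VWC = 0.30


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


def index_a(t_max: float, params: LogisticParams = PUBLISHED_PARAMS["A"]) -> float:
    """Temperature index Y'_A from daily maximum air temperature (°C)."""
    return params(_require_finite("t_max", t_max))


def index_b(rh_min: float, params: LogisticParams = PUBLISHED_PARAMS["B"]) -> float:
    """Humidity index Y'_B from daily minimum relative humidity (fraction).

    Rejects values outside [0, 1] to guard against percent-vs-fraction
    mistakes — the curve's coefficients are only meaningful for fractions.
    """
    rh_min = _require_finite("rh_min", rh_min)
    if not 0.0 <= rh_min <= 1.0:
        raise ValidationError(f"rh_min must be a fraction in [0, 1], got {rh_min}")
    return params(rh_min)


def index_c(
    precip_mm: float,
    t_run: int,
    params: LogisticParams = PUBLISHED_PARAMS["C"],
) -> float:
    """Precipitation index Y'_C from daily precipitation and a day counter.

    For daily precipitation up to 10 mm the logistic scoring of the amount is
    augmented by ``5 * t_run``; above 10 mm the index collapses to
    ``5 * (t_run - 1)``.  The result is clamped to [0, 50].

    ``t_run`` is a consecutive-day counter carried in from daily aggregation.
    Which run it counts (dry days by default, or wet days) is decided
    upstream; see :class:`IndexEquations`.
    """
    precip_mm = _require_finite("precip_mm", precip_mm)
    if precip_mm < 0:
        raise ValidationError("precip_mm must be non-negative")
    if t_run < 0:
        raise ValidationError("t_run must be non-negative")
    if precip_mm <= HEAVY_RAIN_MM:
        raw = params(precip_mm) + 5.0 * t_run
    else:
        raw = 5.0 * (t_run - 1)
    return min(max(raw, 0.0), C_MAX)


def index_d(wind_max: float, params: LogisticParams = PUBLISHED_PARAMS["D"]) -> float:
    """Wind index Y'_D from daily maximum wind speed (m/s)."""
    wind_max = _require_finite("wind_max", wind_max)
    if wind_max < 0:
        raise ValidationError("wind_max must be non-negative")
    return params(wind_max)


def index_e2(humus_vwc: float) -> float:
    """Litter-layer soil-moisture correction Y'_E2.

    Piecewise in the humus-layer volumetric water content (fraction):
    0 below 5%, linear ``4 - 80*vwc`` between 5% and 30%, and −20 at and
    above 30%.  Continuous at both breakpoints.
    """
    humus_vwc = _require_finite("humus_vwc", humus_vwc)
    if not 0.0 <= humus_vwc <= 1.0:
        raise ValidationError(f"humus_vwc must be a fraction in [0, 1], got {humus_vwc}")
    if humus_vwc < E2_DRY_VWC:
        return 0.0
    if humus_vwc < E2_WET_VWC:
        return 4.0 - 80.0 * humus_vwc
    return -20.0


_MD = tuple[int, int]  # (month, day)


def _md(value) -> _MD:
    """Normalise a month-day spec: (m, d) tuple or 'MM-DD' string."""
    if isinstance(value, str):
        m, d = value.split("-")
        return int(m), int(d)
    m, d = value
    return int(m), int(d)


@dataclass(frozen=True)
class PhenologyConfig:
    """Calendar configuration of the vegetation-cover term Y'_E1.

    The term is 0 outside the fire season, rises to ``fire_season_value``
    inside it and to ``core_fire_season_value`` in the core fire season.
    Ranges are (start, end) month-day pairs, inclusive on both ends; core
    ranges must lie inside fire-season ranges.  Defaults cover a northern
    spring/autumn fire season with a mid-March-to-May core.
    """

    off_season_value: float = 0.0
    fire_season_value: float = 15.0
    core_fire_season_value: float = 20.0
    fire_season_ranges: tuple[tuple[_MD, _MD], ...] = (
        ((3, 1), (6, 15)),
        ((9, 15), (11, 30)),
    )
    core_season_ranges: tuple[tuple[_MD, _MD], ...] = (((3, 15), (5, 31)),)

    def __post_init__(self):
        if min(self.off_season_value, self.fire_season_value,
               self.core_fire_season_value) < 0:
            raise ValidationError("phenology values must be non-negative")
        fire = tuple((_md(a), _md(b)) for a, b in self.fire_season_ranges)
        core = tuple((_md(a), _md(b)) for a, b in self.core_season_ranges)
        object.__setattr__(self, "fire_season_ranges", fire)
        object.__setattr__(self, "core_season_ranges", core)
        for rng in core:
            if not any(f[0] <= rng[0] and rng[1] <= f[1] for f in fire):
                raise ValidationError(
                    f"core range {rng} not contained in any fire-season range"
                )

    @staticmethod
    def _in_range(md: _MD, rng: tuple[_MD, _MD]) -> bool:
        start, end = rng
        if start <= end:
            return start <= md <= end
        return md >= start or md <= end  # wraps around the new year

    def value_for(self, date: dt.date) -> float:
        md = (date.month, date.day)
        if any(self._in_range(md, r) for r in self.core_season_ranges):
            return self.core_fire_season_value
        if any(self._in_range(md, r) for r in self.fire_season_ranges):
            return self.fire_season_value
        return self.off_season_value


def index_e1(date, config: PhenologyConfig | None = None) -> float:
    """Phenology term Y'_E1 for a calendar date."""
    config = config or PhenologyConfig()
    if isinstance(date, str):
        try:
            date = dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValidationError(f"malformed date {date!r}") from exc
    if isinstance(date, dt.datetime):
        date = date.date()
    if not isinstance(date, dt.date):
        raise ValidationError(f"not a date: {date!r}")
    return config.value_for(date)


# Grade table: (upper bound on the rounded composite, grade).
_GRADE_BOUNDS = ((25, 1), (50, 2), (72, 3), (90, 4))


def classify_grade(total: float) -> int:
    """Map a composite index value to fire-danger grade 1–5.

    The published thresholds are integer intervals (≤25 → I, 26–50 → II,
    51–72 → III, 73–90 → IV, ≥91 → V); real-valued totals are rounded
    half-up to the nearest integer before lookup so the printed thresholds
    apply verbatim.
    """
    rounded = math.floor(total + 0.5)
    for bound, grade in _GRADE_BOUNDS:
        if rounded <= bound:
            return grade
    return 5


@dataclass(frozen=True)
class DailyFireAssessment:
    """Component indices, composite and grade for one station-day."""

    date: dt.date
    y_a: float
    y_b: float
    y_c: float
    y_d: float
    y_e1: float
    y_e2: float
    total: float
    grade: int
    quality_flag: bool = False  # True when the day had a data gap

    def as_row(self) -> dict:
        return {
            "date": self.date.isoformat(),
            "y_a": self.y_a, "y_b": self.y_b, "y_c": self.y_c,
            "y_d": self.y_d, "y_e1": self.y_e1, "y_e2": self.y_e2,
            "total": self.total, "grade": self.grade,
            "quality_flag": self.quality_flag,
        }


def composite_and_grade(
    y_a: float, y_b: float, y_c: float, y_d: float, y_e1: float, y_e2: float
) -> tuple[float, int]:
    """Sum the six components and classify the result into a grade."""
    total = y_a + y_b + y_c + y_d + y_e1 + y_e2
    return total, classify_grade(total)


class IndexEquations:
    """Bundle of the six component equations with one parameter source.

    Parameters
    ----------
    params : mapping of index id to LogisticParams, optional
        Scoring-curve coefficients for A–D.  Defaults to the published set.
    phenology : PhenologyConfig, optional
    c_run_counter : {"dry", "wet"}
        Which consecutive-day counter feeds the precipitation index's
        ``t`` term.  Default ``"dry"``: the count of consecutive rain-free
        days, so the dry-spell bonus grows while no rain falls.
    """

    def __init__(
        self,
        params: Mapping[str, LogisticParams] | None = None,
        phenology: PhenologyConfig | None = None,
        c_run_counter: Literal["dry", "wet"] = "dry",
    ):
        self.params = dict(params or PUBLISHED_PARAMS)
        missing = {"A", "B", "C", "D"} - set(self.params)
        if missing:
            raise ValidationError(f"missing params for indices {sorted(missing)}")
        self.phenology = phenology or PhenologyConfig()
        if c_run_counter not in ("dry", "wet"):
            raise ValidationError("c_run_counter must be 'dry' or 'wet'")
        self.c_run_counter = c_run_counter

    @classmethod
    def published(cls, **kwargs) -> "IndexEquations":
        """Equations with the published coefficients."""
        return cls(PUBLISHED_PARAMS, **kwargs)

    @classmethod
    def from_fits(
        cls, fits: Mapping[str, StepLogisticResults], **kwargs
    ) -> "IndexEquations":
        """Equations with refitted coefficients (see :func:`refit_builtin`)."""
        params = {
            sid: LogisticParams(f.alpha, f.beta, f.k) for sid, f in fits.items()
        }
        return cls(params, **kwargs)

    def assess(
        self,
        date,
        t_max: float,
        rh_min: float,
        precip_mm: float,
        wind_max: float,
        humus_vwc: float,
        dry_run: int | None = None,
        wet_run: int | None = None,
        quality_flag: bool = False,
    ) -> DailyFireAssessment:
        """Score one day and classify its fire-weather grade."""
        if isinstance(date, str):
            date = dt.date.fromisoformat(date)
        run = dry_run if self.c_run_counter == "dry" else wet_run
        if run is None:
            raise StateError(
                f"{self.c_run_counter}_run counter is unset; "
                "run update_runs over the daily summaries first"
            )
        y_a = index_a(t_max, self.params["A"])
        y_b = index_b(rh_min, self.params["B"])
        y_c = index_c(precip_mm, run, self.params["C"])
        y_d = index_d(wind_max, self.params["D"])
        y_e1 = index_e1(date, self.phenology)
        y_e2 = index_e2(humus_vwc)
        total, grade = composite_and_grade(y_a, y_b, y_c, y_d, y_e1, y_e2)
        return DailyFireAssessment(
            date, y_a, y_b, y_c, y_d, y_e1, y_e2, total, grade, quality_flag
        )
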