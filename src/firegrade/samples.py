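"""Step-interval score sample sets for the four meteorological danger indices.

China's fire-danger standard scores four daily meteorological quantities on
step intervals: daily maximum air temperature (index A), daily minimum
relative humidity (B), daily precipitation amount (C) and daily maximum wind
speed (D).  Each index has a saturation score K (20, 20, 10 and 40
respectively).  The interval midpoints and their scores form a small (x, y)
sample set per index; fitting a logistic curve through them replaces the
discontinuous steps with a smooth scoring function.

Relative humidity is held as a fraction in [0, 1] throughout the package;
percent is accepted only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ValidationError

__all__ = ["StepSampleSet", "builtin_sample_sets", "load_sample_sets", "dump_sample_sets"]

#: Units of the abscissa per index.
X_UNITS = {
    "A": "degC",
    "B": "fraction RH",
    "C": "mm precipitation",
    "D": "m/s wind",
}


@dataclass(frozen=True)
class StepSampleSet:
    """Score sample set of one danger index.

    Parameters
    ----------
    index_id : str
        One of ``"A"``, ``"B"``, ``"C"``, ``"D"``.
    pairs : sequence of (float, float)
        ``(x, y)`` pairs: the variable value (interval midpoint) and the
        step score assigned to it.  ``x`` must be strictly monotone.
    k : float
        Saturation score of the index; all ``y`` lie in ``[0, k]``.
    x_units : str
        Unit label for ``x``.
    """

    index_id: str
    pairs: tuple[tuple[float, float], ...]
    k: float
    x_units: str = ""

    def __post_init__(self):
        if self.index_id not in ("A", "B", "C", "D"):
            raise ValidationError(f"unknown index_id {self.index_id!r}")
        if not self.pairs:
            raise ValidationError("sample set must be non-empty")
        if not self.k > 0:
            raise ValidationError("saturation score k must be positive")
        xs = [p[0] for p in self.pairs]
        ys = [p[1] for p in self.pairs]
        diffs = [b - a for a, b in zip(xs, xs[1:])]
        if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
            raise ValidationError("x values must be strictly monotone")
        if any(y < 0 or y > self.k for y in ys):
            raise ValidationError("all scores must lie in [0, k]")
        object.__setattr__(self, "pairs", tuple((float(x), float(y)) for x, y in self.pairs))

    @property
    def x(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def y(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


# Published step-interval sample sets of the national standard, with relative
# humidity converted from percent to fraction.  K = {20, 20, 10, 40}.
_BUILTIN = {
    "A": StepSampleSet(
        "A",
        ((2.5, 0), (7.5, 4), (12.5, 8), (17.5, 12), (22.5, 16), (27.5, 20)),
        20.0,
        X_UNITS["A"],
    ),
    "B": StepSampleSet(
        "B",
        ((0.75, 0), (0.65, 4), (0.55, 8), (0.45, 12), (0.35, 16), (0.25, 20)),
        20.0,
        X_UNITS["B"],
    ),
    "C": StepSampleSet(
        "C",
        ((0.3, 10), (0.9, 8), (2.0, 6), (3.5, 4), (5.0, 2), (7.5, 0)),
        10.0,
        X_UNITS["C"],
    ),
    "D": StepSampleSet(
        "D",
        (
            (0.1, 0), (0.9, 5), (2.5, 10), (6.7, 15), (9.4, 20),
            (12.3, 25), (15.5, 30), (19.0, 35), (20.7, 40),
        ),
        40.0,
        X_UNITS["D"],
    ),
}


def builtin_sample_sets() -> dict[str, StepSampleSet]:
    """Return the four built-in step-interval sample sets keyed by index id."""
    return dict(_BUILTIN)


def _sets_from_mapping(data: Mapping) -> dict[str, StepSampleSet]:
    out = {}
    for index_id, spec in data.items():
        out[str(index_id)] = StepSampleSet(
            index_id=str(index_id),
            pairs=tuple((float(x), float(y)) for x, y in spec["pairs"]),
            k=float(spec["k"]),
            x_units=str(spec.get("x_units", X_UNITS.get(str(index_id), ""))),
        )
    return out


def load_sample_sets(path: str | Path) -> dict[str, StepSampleSet]:
    """Load sample sets from a YAML or JSON config file.

    Expected layout::

        A:
          k: 20
          pairs: [[2.5, 0], [7.5, 4], ...]
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _sets_from_mapping(data)


def dump_sample_sets(sets: Mapping[str, StepSampleSet], path: str | Path) -> None:
    """Write sample sets to a YAML or JSON file (dialect from the suffix)."""
    path = Path(path)
    data = {
        sid: {"k": s.k, "x_units": s.x_units, "pairs": [list(p) for p in s.pairs]}
        for sid, s in sets.items()
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
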