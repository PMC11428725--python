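"""Three-level full factorial designs and coded-variable transforms.

A factor with natural levels (low, mid, high) is mapped to the coded scale by

    coded = (x - (low + high) / 2) / ((high - low) / 2)

so that ``coded(low) = -1`` and ``coded(high) = +1`` exactly.  The mid level
need not sit at the centre of the interval: in the wood-chip extraction design
the time factor has levels 3/6/24 h, so 6 h codes to -5/7, not 0.  Coded
settings are stored at full floating precision throughout.

The regression model matrix for a three-factor design carries eight columns in
a fixed order: intercept, the three main effects, the three two-way products
and the three-way product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateFactorError",
    "FactorSpec",
    "DesignPoint",
    "ModelMatrix",
    "STUDY_FACTORS",
    "code_value",
    "decode_value",
    "build_full_factorial",
    "model_matrix",
    "interaction_terms",
]


class DegenerateFactorError(ValueError):
    """Raised when a factor's low and high levels coincide."""


@dataclass(frozen=True)
class FactorSpec:
    """An experimental factor with three natural-unit levels.

    Parameters
    ----------
    name : str
        Column name used in datasets and model-term labels.
    low, mid, high : float
        The three levels in natural units; must be strictly increasing.
    units : str
        Display units (e.g. ``"degC"``, ``"%"``, ``"h"``).
    """

    name: str
    low: float
    mid: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.mid < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < mid < high, "
                f"got {self.low}, {self.mid}, {self.high}"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    @property
    def levels(self) -> tuple[float, float, float]:
        return (self.low, self.mid, self.high)


def code_value(factor: FactorSpec, x: float) -> float:
    """Map a natural-unit value onto the coded [-1, 1] scale.

    Values outside [low, high] are permitted (extrapolation) and simply code
    to values outside [-1, 1].
    """
    if factor.half_range == 0:
        raise DegenerateFactorError(f"factor {factor.name!r} has zero range")
    return (x - factor.center) / factor.half_range


def decode_value(factor: FactorSpec, c: float) -> float:
    """Inverse of :func:`code_value`: coded scale back to natural units."""
    if factor.half_range == 0:
        raise DegenerateFactorError(f"factor {factor.name!r} has zero range")
    return factor.center + c * factor.half_range


@dataclass(frozen=True)
class DesignPoint:
    """One run of the design: natural-unit settings and their coded images."""

    settings: Mapping[str, float]
    coded: Mapping[str, float]

    @classmethod
    def from_natural(cls, factors: Sequence[FactorSpec], values: Mapping[str, float] | Sequence[float]) -> "DesignPoint":
        if not isinstance(values, Mapping):
            values = {f.name: v for f, v in zip(factors, values, strict=True)}
        settings = {f.name: float(values[f.name]) for f in factors}
        coded = {f.name: code_value(f, settings[f.name]) for f in factors}
        return cls(settings=settings, coded=coded)

    @classmethod
    def from_coded(cls, factors: Sequence[FactorSpec], coded_values: Mapping[str, float] | Sequence[float]) -> "DesignPoint":
        if not isinstance(coded_values, Mapping):
            coded_values = {f.name: v for f, v in zip(factors, coded_values, strict=True)}
        coded = {f.name: float(coded_values[f.name]) for f in factors}
        settings = {f.name: decode_value(f, coded[f.name]) for f in factors}
        return cls(settings=settings, coded=coded)

    def coded_vector(self, factor_names: Sequence[str]) -> np.ndarray:
        return np.array([self.coded[n] for n in factor_names], dtype=float)

    @property
    def is_extrapolation(self) -> bool:
        """True when any coded coordinate lies outside [-1, 1] (beyond fp slack)."""
        return any(abs(c) > 1.0 + 1e-12 for c in self.coded.values())


#: The wood-chip extraction study factors: temperature 20/50/80 degC,
#: ethanol fraction 0/20/40 % (v/v in water), extraction time 3/6/24 h.
STUDY_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("temperature", 20.0, 50.0, 80.0, "degC"),
    FactorSpec("ethanol", 0.0, 20.0, 40.0, "%"),
    FactorSpec("time", 3.0, 6.0, 24.0, "h"),
)


def build_full_factorial(factors: Sequence[FactorSpec]) -> list[DesignPoint]:
    """All 3^k level combinations, first factor varying slowest."""
    if len(factors) == 0:
        raise ValueError("at least one factor is required")
    points = []
    for combo in itertools.product(*(f.levels for f in factors)):
        points.append(DesignPoint.from_natural(factors, dict(zip((f.name for f in factors), combo))))
    return points


def interaction_terms(factor_names: Sequence[str]) -> tuple[str, ...]:
    """Term labels for the intercept + mains + all product interactions model."""
    names = list(factor_names)
    terms: list[str] = ["intercept"] + names
    for order in range(2, len(names) + 1):
        for combo in itertools.combinations(names, order):
            terms.append(":".join(combo))
    return tuple(terms)


@dataclass(frozen=True)
class ModelMatrix:
    """Regression design matrix with named columns.

    ``values[i, j]`` is the j-th term evaluated at the i-th design point; the
    intercept column is all ones and every interaction column is the
    elementwise product of its parent coded columns.
    """

    terms: tuple[str, ...]
    values: np.ndarray
    factor_names: tuple[str, ...] = field(default=())

    def __len__(self) -> int:
        return self.values.shape[0]

    def column(self, term: str) -> np.ndarray:
        return self.values[:, self.terms.index(term)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.terms))


def model_matrix(points: Iterable[DesignPoint], factor_names: Sequence[str] | None = None) -> ModelMatrix:
    """Build the intercept + main-effects + all-interactions matrix.

    For three factors this is the eight-column matrix
    [1, X1, X2, X3, X1X2, X1X3, X2X3, X1X2X3] used by the factorial
    regression model.
    """
    points = list(points)
    if not points:
        raise ValueError("no design points given")
    if factor_names is None:
        factor_names = list(points[0].coded.keys())
    names = list(factor_names)
    coded = np.array([[p.coded[n] for n in names] for p in points], dtype=float)
    cols = [np.ones(len(points))]
    for x in coded.T:
        cols.append(x)
    for order in range(2, len(names) + 1):
        for combo in itertools.combinations(range(len(names)), order):
            cols.append(np.prod(coded[:, combo], axis=1))
    return ModelMatrix(
        terms=interaction_terms(names),
        values=np.column_stack(cols),
        factor_names=tuple(names),
    )


def design_frame(points: Sequence[DesignPoint], factors: Sequence[FactorSpec]) -> pd.DataFrame:
    """Natural and coded settings of a design as a table (CSV-exportable)."""
    rows = {}
    for f in factors:
        rows[f.name] = [p.settings[f.name] for p in points]
    for f in factors:
        rows[f"{f.name}_coded"] = [p.coded[f.name] for p in points]
    frame = pd.DataFrame(rows)
    frame.insert(0, "run", np.arange(1, len(points) + 1))
    return frame
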