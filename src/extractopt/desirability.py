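"""Multi-response optimization by composite desirability.

Each predicted response is mapped onto [0, 1] by the larger-is-better
desirability transform

    d(y) = 0                      y <= L
    d(y) = ((y - L)/(T - L))^w    L < y < T
    d(y) = 1                      y >= T

and a candidate setting is scored by the geometric mean of the per-response
desirabilities (composite desirability D).  Unless stated otherwise, L and T
default to the observed minimum and maximum of each response in the dataset
and w = 1; predictions above T are capped at d = 1 so that extrapolated model
maxima remain feasible.

The optimizer screens an 11x11x11 grid of coded settings over the factor
cube, then refines the best grid points with Nelder-Mead simplex searches
clamped to the cube.  It is deterministic for a fixed seed; exact ties in D
are broken toward the lexicographically smallest coded coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize as sciopt

from .design import DesignPoint, FactorSpec
from .dataset import ResponseTable
from .ffd_model import FitResult

__all__ = [
    "DesirabilityGoal",
    "OptimumResult",
    "desirability_maximize",
    "composite_desirability",
    "goals_from_table",
    "predictors_from_fits",
    "optimize",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class DesirabilityGoal:
    """Larger-is-better goal: d = 0 at/below ``lower``, 1 at/above ``target``."""

    response_name: str
    lower: float
    target: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.target:
            raise ValueError(
                f"goal for {self.response_name!r}: lower ({self.lower}) must be "
                f"below target ({self.target})"
            )
        if self.weight <= 0:
            raise ValueError("weight must be positive")


def desirability_maximize(y: float, goal: DesirabilityGoal) -> float:
    """The one-sided desirability transform for a maximize goal."""
    if y <= goal.lower:
        return 0.0
    if y >= goal.target:
        return 1.0
    return float(((y - goal.lower) / (goal.target - goal.lower)) ** goal.weight)


def composite_desirability(ds: Sequence[float]) -> float:
    """Geometric mean of per-response desirabilities; 0 if any is 0."""
    ds = np.asarray(ds, dtype=float)
    if ds.size == 0:
        raise ValueError("no desirabilities given")
    if np.any((ds < 0) | (ds > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    if np.any(ds == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(ds))))


def goals_from_table(table: ResponseTable, responses: Sequence[str], weight: float = 1.0) -> list[DesirabilityGoal]:
    """Maximize goals with L/T set to each response's observed min/max."""
    goals = []
    for r in responses:
        y = table.response(r)
        goals.append(DesirabilityGoal(r, float(y.min()), float(y.max()), weight))
    return goals


def predictors_from_fits(fits: Mapping[str, FitResult]) -> dict[str, Callable[[np.ndarray], float]]:
    """Coded-space prediction functions from fitted factorial models."""

    def make(fit: FitResult) -> Callable[[np.ndarray], float]:
        names = fit.matrix.factor_names

        def f(coded: np.ndarray) -> float:
            from .design import model_matrix

            point = DesignPoint(
                settings={n: np.nan for n in names},
                coded=dict(zip(names, np.asarray(coded, dtype=float))),
            )
            return float(model_matrix([point], names).values[0] @ fit.coef_vector)

        return f

    return {name: make(fit) for name, fit in fits.items()}


@dataclass
class OptimumResult:
    """Best factor settings found and their desirability breakdown."""

    settings: DesignPoint
    per_response_fit: dict[str, float]
    per_response_d: dict[str, float]
    composite_D: float
    feasible: bool = True
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "optimal settings: "
            + ", ".join(f"{k} = {v:.3f}" for k, v in self.settings.settings.items()),
        ]
        for r, y in self.per_response_fit.items():
            lines.append(f"  {r}: predicted {y:.2f}  (d = {self.per_response_d[r]:.4f})")
        lines.append(f"composite desirability D = {self.composite_D:.4f}")
        return "\n".join(lines)


def _lex_less(a: np.ndarray, b: np.ndarray) -> bool:
    for x, y in zip(a, b):
        if x < y - _TIE_TOL:
            return True
        if x > y + _TIE_TOL:
            return False
    return False


def optimize(
    predictors: Mapping[str, Callable[[np.ndarray], float]],
    goals: Sequence[DesirabilityGoal],
    factors: Sequence[FactorSpec],
    *,
    grid: int = 11,
    n_starts: int = 20,
    seed: int = 0,
) -> OptimumResult:
    """Maximize composite desirability over the coded factor cube [-1, 1]^k.

    A ``grid``^k coded grid is screened, the ``n_starts`` best grid points are
    refined with Nelder-Mead (arguments clamped to the cube), and the overall
    best point is returned.  Deterministic for fixed ``seed`` (the seed only
    jitters degenerate initial simplices).
    """
    if not goals:
        raise ValueError("at least one goal is required")
    missing = [g.response_name for g in goals if g.response_name not in predictors]
    if missing:
        raise KeyError(f"no predictor for goal response(s): {missing}")
    k = len(factors)
    rng = np.random.default_rng(seed)

    def per_response(coded: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
        fits = {g.response_name: predictors[g.response_name](coded) for g in goals}
        ds = {g.response_name: desirability_maximize(fits[g.response_name], g) for g in goals}
        return fits, ds

    def score(coded: np.ndarray) -> float:
        _, ds = per_response(coded)
        return composite_desirability(list(ds.values()))

    axes = [np.linspace(-1.0, 1.0, grid)] * k
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
    grid_scores = np.array([score(c) for c in mesh])

    order = np.argsort(-grid_scores, kind="stable")
    starts = mesh[order[:n_starts]]
    best_grid_D = float(grid_scores[order[0]])

    def neg(coded: np.ndarray) -> float:
        return -score(np.clip(coded, -1.0, 1.0))

    best_c = np.clip(mesh[order[0]], -1.0, 1.0)
    best_D = best_grid_D
    n_evals = len(mesh)
    for s in starts:
        x0 = s + rng.uniform(-1e-9, 1e-9, size=k)  # break exact-corner simplices
        res = sciopt.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400 * k},
        )
        n_evals += res.nfev
        c = np.clip(res.x, -1.0, 1.0)
        D = score(c)
        if D > best_D + _TIE_TOL or (abs(D - best_D) <= _TIE_TOL and _lex_less(c, best_c)):
            best_D, best_c = D, c

    fits, ds = per_response(best_c)
    feasible = best_D > 0.0
    point = DesignPoint.from_coded(factors, dict(zip((f.name for f in factors), best_c)))
    return OptimumResult(
        settings=point,
        per_response_fit=fits,
        per_response_d=ds,
        composite_D=best_D,
        feasible=feasible,
        diagnostics={
            "best_grid_D": best_grid_D,
            "n_evaluations": int(n_evals),
            "n_starts": int(len(starts)),
            "seed": seed,
        },
    )
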