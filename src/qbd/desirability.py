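"""Derringer-Suich desirability functions and multi-response optimization.

Each response y is mapped to a desirability d in [0, 1] by a ramp toward its
goal; the composite desirability is the importance-weighted geometric mean

    D = (prod d_i^r_i)^(1 / sum r_i),

which is zero as soon as any single response is fully undesirable. The
optimal formulation is the point of the coded factor cube maximizing D,
found by a deterministic multi-start search: a fixed lattice of starts, each
refined by bounded Nelder-Mead.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .design import FactorSpec, decode_factors
from .rsm import FittedModel, predict

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "desirability_value",
    "composite_desirability",
    "optimize",
    "prediction_error",
]

DIRECTIONS = ("maximize", "minimize", "target", "in_range")


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal for one response: direction, bounds and weighting.

    ``lower``/``upper`` are the anchor points of the ramp — conventionally
    the observed response range in the design — and ``target`` is required
    only for the two-sided ``target`` direction. ``weight`` curves the ramp
    (d ** weight); ``importance`` is the exponent r_i in the composite.
    """

    response_name: str
    direction: str
    lower: float
    upper: float
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if not self.lower < self.upper:
            raise ValueError(
                f"goal {self.response_name!r}: lower ({self.lower}) must be < upper ({self.upper})"
            )
        if self.weight <= 0 or self.importance <= 0:
            raise ValueError(f"goal {self.response_name!r}: weight and importance must be > 0")
        if self.direction == "target":
            if self.target is None or not self.lower < self.target < self.upper:
                raise ValueError(
                    f"goal {self.response_name!r}: target direction needs lower < target < upper"
                )


def desirability_value(y: float, goal: DesirabilityGoal) -> float:
    """Per-response desirability d(y) in [0, 1] under the goal's ramp."""
    lo, hi, w = goal.lower, goal.upper, goal.weight
    span = hi - lo
    if goal.direction == "maximize":
        base = (y - lo) / span
    elif goal.direction == "minimize":
        base = (hi - y) / span
    elif goal.direction == "target":
        t = goal.target
        base = (y - lo) / (t - lo) if y <= t else (hi - y) / (hi - t)
    else:  # in_range
        return 1.0 if lo <= y <= hi else 0.0
    return float(np.clip(base, 0.0, 1.0) ** w)


def composite_desirability(d: dict[str, float], importance: dict[str, float] | None = None) -> float:
    """Importance-weighted geometric mean of per-response desirabilities."""
    if not d:
        raise ValueError("no desirabilities given")
    values = np.array(list(d.values()), dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    if importance is None:
        r = np.ones_like(values)
    else:
        r = np.array([importance[k] for k in d], dtype=float)
    if np.any(values == 0):
        return 0.0
    return float(np.exp(np.sum(r * np.log(values)) / r.sum()))


@dataclass
class OptimizationResult:
    coded_optimum: np.ndarray
    natural_optimum: dict[str, float]
    predicted_responses: dict[str, float]
    per_response_d: dict[str, float]
    composite_D: float
    n_starts: int = 0
    warnings: list[str] = field(default_factory=list)


# Fixed start lattice: 5 levels per factor, no stochastic restarts.
_START_LEVELS = (-1.0, -0.5, 0.0, 0.5, 1.0)
_NM_OPTIONS = {"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000}


def optimize(
    models: list[FittedModel],
    goals: list[DesirabilityGoal],
    bounds: tuple[float, float] = (-1.0, 1.0),
    specs: list[FactorSpec] | None = None,
) -> OptimizationResult:
    """Maximize composite desirability over the coded factor cube.

    Deterministic: every point of a fixed 5^k start lattice is refined by
    Nelder-Mead within ``bounds``; the best refined point wins, earlier
    starts winning ties. ``specs`` (defaulting to none) adds the optimum in
    natural units.
    """
    by_name = {m.response_name: m for m in models}
    missing = [g.response_name for g in goals if g.response_name not in by_name]
    if missing:
        raise ValueError(f"no fitted model for goal(s) {missing}")
    if not goals:
        raise ValueError("no goals given")
    k = len(models[0].factor_names)
    lo, hi = bounds
    importance = {g.response_name: g.importance for g in goals}

    def neg_D(x: np.ndarray) -> float:
        x = np.clip(x, lo, hi)
        d = {
            g.response_name: desirability_value(predict(by_name[g.response_name], x), g)
            for g in goals
        }
        return -composite_desirability(d, importance)

    best_x, best_D = None, -np.inf
    n_starts = 0
    for start in itertools.product(_START_LEVELS, repeat=k):
        n_starts += 1
        res = minimize(
            neg_D,
            np.array(start, dtype=float),
            method="Nelder-Mead",
            bounds=[(lo, hi)] * k,
            options=_NM_OPTIONS,
        )
        if -res.fun > best_D:
            best_D, best_x = -res.fun, np.clip(res.x, lo, hi)

    notes = []
    if best_D <= 0:
        notes.append("all starts yielded zero composite desirability")
        warnings.warn(notes[-1], stacklevel=2)

    preds = {g.response_name: float(predict(by_name[g.response_name], best_x)) for g in goals}
    per_d = {g.response_name: desirability_value(preds[g.response_name], g) for g in goals}
    factor_names = models[0].factor_names
    natural = (
        {s.name: decode_factors(float(x), s) for s, x in zip(specs, best_x)}
        if specs is not None
        else {name: float(x) for name, x in zip(factor_names, best_x)}
    )
    return OptimizationResult(
        coded_optimum=best_x,
        natural_optimum=natural,
        predicted_responses=preds,
        per_response_d=per_d,
        composite_D=composite_desirability(per_d, importance),
        n_starts=n_starts,
        warnings=notes,
    )


def prediction_error(actual: float, predicted: float) -> float:
    """Signed percent prediction error, 100 * (actual - predicted) / actual."""
    if actual == 0:
        raise ValueError("actual value is zero; percent error undefined")
    return 100.0 * (actual - predicted) / actual
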