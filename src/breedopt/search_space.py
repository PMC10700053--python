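"""Feasible designs of a progeny-testing breeding program.

A design (parametrization) is three non-negative integers:

* ``x1`` — number of test daughters (females phenotyped to estimate
  their sires' breeding values),
* ``x2`` — number of test bulls entering progeny testing each year,
* ``x3`` — number of sires selected from the test bulls by truncation
  on estimated breeding value.

An annual budget with per-head housing costs constrains ``x1`` and
``x2`` (``cost_cow * x1 + cost_bull * x2 <= total``); selected sires are
drawn from already-housed test bulls and carry no extra cost.  Since any
budget not spent on bulls is best spent on daughters (more daughters =
more accurate progeny tests), ``x1`` is fully determined by ``x2``
through budget exhaustion, leaving ``(x2, x3)`` as the free dimensions
of the search space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InfeasibleError",
    "BudgetModel",
    "ParameterBounds",
    "Parametrization",
    "allocate_daughters",
    "is_feasible",
    "sample_parametrizations",
    "enumerate_grid",
]


class InfeasibleError(ValueError):
    """Raised when a design (or a whole region) violates hard constraints."""


@dataclass(frozen=True)
class BudgetModel:
    """Annual budget and per-head housing costs (currency units per year)."""

    total_budget: float = 10_000_000.0
    cost_per_cow: float = 4_000.0
    cost_per_bull: float = 3_000.0

    def __post_init__(self) -> None:
        if min(self.total_budget, self.cost_per_cow, self.cost_per_bull) <= 0:
            raise ValueError("budget and per-head costs must be strictly positive")

    def cost(self, x1: int, x2: int) -> float:
        return self.cost_per_cow * x1 + self.cost_per_bull * x2


@dataclass(frozen=True)
class ParameterBounds:
    """Inclusive integer ranges for test bulls (x2) and selected sires (x3)."""

    x2_min: int = 100
    x2_max: int = 700
    x3_min: int = 3
    x3_max: int = 30

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.x2_min, self.x2_max, "x2"),
            (self.x3_min, self.x3_max, "x3"),
        ):
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{name} bounds must be positive integers")
            if lo > hi:
                raise ValueError(f"{name}_min exceeds {name}_max")


@dataclass(frozen=True)
class Parametrization:
    """One candidate design: (x1 test daughters, x2 test bulls, x3 sires)."""

    x1: int
    x2: int
    x3: int

    def __post_init__(self) -> None:
        if min(self.x1, self.x2, self.x3) < 0:
            raise ValueError("x1, x2, x3 must be non-negative integers")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.x1, self.x2, self.x3)


def allocate_daughters(x2: int, budget: BudgetModel | None = None) -> int:
    """Largest x1 affordable after housing ``x2`` test bulls.

    Floor of the residual budget divided by the cow cost, so that no
    further daughter fits: ``total - cost(x1, x2) < cost_per_cow``.
    """
    budget = budget or BudgetModel()
    if x2 < 0:
        raise ValueError("x2 must be non-negative")
    residual = budget.total_budget - budget.cost_per_bull * x2
    if residual < 0:
        raise InfeasibleError(
            f"housing {x2} bulls alone costs {budget.cost_per_bull * x2:,.0f}, "
            f"exceeding the budget of {budget.total_budget:,.0f}"
        )
    return int(residual // budget.cost_per_cow)


def is_feasible(
    p: Parametrization,
    bounds: ParameterBounds | None = None,
    budget: BudgetModel | None = None,
) -> bool:
    """True iff ``p`` satisfies bounds, x3 <= x2 and the budget constraint."""
    bounds = bounds or ParameterBounds()
    budget = budget or BudgetModel()
    if p.x3 > p.x2:
        return False
    if not (bounds.x2_min <= p.x2 <= bounds.x2_max):
        return False
    if not (bounds.x3_min <= p.x3 <= bounds.x3_max):
        return False
    return budget.cost(p.x1, p.x2) <= budget.total_budget


def _feasible_x2_max(bounds: ParameterBounds, budget: BudgetModel) -> int:
    """Largest in-bounds x2 whose bull cost alone fits the budget."""
    cap = int(budget.total_budget // budget.cost_per_bull)
    return min(bounds.x2_max, cap)


def sample_parametrizations(
    n: int,
    bounds: ParameterBounds | None = None,
    budget: BudgetModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[Parametrization]:
    """Draw ``n`` designs uniformly over the feasible (x2, x3) region.

    x2 and x3 are discrete-uniform on their inclusive bounds; draws with
    x3 > x2 (or bull cost alone over budget) are rejected and redrawn,
    which preserves uniformity on the feasible region.  x1 is then
    allocated from the residual budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bounds = bounds or ParameterBounds()
    budget = budget or BudgetModel()
    x2_hi = _feasible_x2_max(bounds, budget)
    if x2_hi < bounds.x2_min or bounds.x3_min > x2_hi:
        raise InfeasibleError("feasible (x2, x3) region is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    x2_out = np.empty(n, dtype=np.int64)
    x3_out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        m = n - filled
        x2 = rng.integers(bounds.x2_min, bounds.x2_max + 1, size=m)
        x3 = rng.integers(bounds.x3_min, bounds.x3_max + 1, size=m)
        ok = (x3 <= x2) & (x2 <= x2_hi)
        k = int(ok.sum())
        x2_out[filled : filled + k] = x2[ok]
        x3_out[filled : filled + k] = x3[ok]
        filled += k

    x1 = (budget.total_budget - budget.cost_per_bull * x2_out) // budget.cost_per_cow
    return [
        Parametrization(int(a), int(b), int(c))
        for a, b, c in zip(x1.astype(np.int64), x2_out, x3_out)
    ]


def enumerate_grid(
    bounds: ParameterBounds | None = None,
    budget: BudgetModel | None = None,
) -> list[Parametrization]:
    """All feasible integer (x2, x3) pairs, lexicographic in (x2, x3)."""
    bounds = bounds or ParameterBounds()
    budget = budget or BudgetModel()
    x2_hi = _feasible_x2_max(bounds, budget)
    out: list[Parametrization] = []
    for x2 in range(bounds.x2_min, x2_hi + 1):
        x1 = allocate_daughters(x2, budget)
        for x3 in range(bounds.x3_min, min(bounds.x3_max, x2) + 1):
            out.append(Parametrization(x1, x2, x3))
    return out
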