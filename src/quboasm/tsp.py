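"""Brute-force tour enumeration and scoring for directed TSP instances.

This is the oracle layer: every heuristic or encoded solver downstream is
validated against exhaustive enumeration of Hamiltonian cycles here.
Rotations of a cycle are identified (start node fixed at 0) but direction
is never collapsed, because overlap weights are asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

from .reads import TSPInstance

__all__ = [
    "Tour",
    "enumerate_unique_tours",
    "tour_cost",
    "optimal_tours",
    "rotations",
]

ENUMERATION_GUARD = 10  # (n-1)! tours; n=10 -> 362,880, still desk-scale


@dataclass(frozen=True)
class Tour:
    """A directed Hamiltonian cycle given as a visiting order.

    ``order`` is a permutation of 0..n-1; the cycle has an edge from
    ``order[k]`` to ``order[(k+1) % n]``, including the closing edge.
    """

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.order)
        if sorted(self.order) != list(range(n)):
            raise ValueError(f"order {self.order} is not a permutation of 0..{n - 1}")

    def __len__(self) -> int:
        return len(self.order)


def enumerate_unique_tours(n: int) -> list[Tour]:
    """All (n-1)! start-fixed directed tours on n nodes.

    Fixing the start at node 0 collapses the n rotations of each cycle
    into one representative; the two directions of a cycle remain
    distinct tours.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return [Tour((0,) + rest) for rest in permutations(range(1, n))]


def tour_cost(tsp: TSPInstance, tour: Tour) -> float:
    """Sum of edge weights along the cycle, closing edge included."""
    n = len(tour)
    if n != tsp.n:
        raise ValueError(f"tour has {n} nodes, instance has {tsp.n}")
    order = tour.order
    return float(
        sum(tsp.weights[order[k], order[(k + 1) % n]] for k in range(n))
    )


def optimal_tours(tsp: TSPInstance, guard: int = ENUMERATION_GUARD) -> list[Tour]:
    """All start-fixed tours attaining the minimum cost, by full enumeration.

    Returns every tie, sorted lexicographically by visiting order.
    Raises for n beyond the factorial-enumeration guard.
    """
    if tsp.n > guard:
        raise ValueError(
            f"n={tsp.n} exceeds enumeration guard {guard}; "
            "use the QUBO solvers for larger instances"
        )
    tours = enumerate_unique_tours(tsp.n)
    costs = [tour_cost(tsp, t) for t in tours]
    best = min(costs)
    return sorted(
        (t for t, c in zip(tours, costs) if c == best),
        key=lambda t: t.order,
    )


def rotations(tour: Tour) -> list[Tour]:
    """The n start-distinguished representations of the same cycle."""
    order = tour.order
    n = len(order)
    return [Tour(order[k:] + order[:k]) for k in range(n)]
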