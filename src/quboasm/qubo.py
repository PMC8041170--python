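"""QUBO encoding of the directed TSP and the exact QUBO <-> Ising transform.

The encoding uses one binary variable per (node, time-slot) pair,
x_{i,p} = 1 iff node i is visited at slot p, so an n-node instance needs
N = n^2 variables.  Variable u = i*n + p is labeled "n{i}t{p}".

Coefficients are stored once per unordered variable pair in the upper
triangle of Q; the objective is

    y = sum_u Q[u][u] x_u  +  sum_{u<v} Q[u][v] x_u x_v.

With this single-entry convention a valid permutation assignment has
energy n*a + (cost of the decoded tour), and the number of nonzero
strict-upper-triangle entries is 2 n^2 (n-1) when all penalties and edge
weights are nonzero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .reads import TSPInstance

__all__ = [
    "QuboModel",
    "IsingModel",
    "tsp_to_qubo",
    "sufficient_penalty",
    "interaction_count",
    "qubo_energy",
    "qubo_to_ising",
    "ising_to_qubo",
    "ising_energy",
]


@dataclass(frozen=True)
class QuboModel:
    """Binary quadratic model with upper-triangular coefficient storage.

    ``Q[u][v]`` is defined for u <= v only; entries below the diagonal are
    zero by convention.  ``n`` is the TSP node count when the model was
    produced by :func:`tsp_to_qubo` (then N = n^2), or ``None`` for a raw
    model.  ``params`` records the (a, b, c) reward/penalty triple used to
    assemble the model, if any.
    """

    Q: np.ndarray
    n: int | None = None
    params: tuple[float, float, float] | None = None
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError(f"Q must be square, got shape {Q.shape}")
        if np.any(Q[np.tril_indices(Q.shape[0], k=-1)] != 0):
            raise ValueError("Q must be upper-triangular (zeros below diagonal)")
        object.__setattr__(self, "Q", Q)
        if self.n is not None and self.n * self.n != Q.shape[0]:
            raise ValueError(f"n={self.n} inconsistent with {Q.shape[0]} variables")
        if not self.labels:
            if self.n is not None:
                object.__setattr__(
                    self,
                    "labels",
                    tuple(
                        f"n{u // self.n}t{u % self.n}" for u in range(Q.shape[0])
                    ),
                )
            else:
                object.__setattr__(
                    self, "labels", tuple(f"x{u}" for u in range(Q.shape[0]))
                )
        if len(self.labels) != Q.shape[0]:
            raise ValueError("labels length must equal variable count")

    @property
    def num_variables(self) -> int:
        return self.Q.shape[0]

    # alias matching the N = n^2 naming used throughout
    @property
    def N(self) -> int:
        return self.Q.shape[0]

    def symmetrize(self) -> np.ndarray:
        """Full symmetric matrix view: each off-diagonal coefficient split
        half-and-half across the two mirror entries (for export only; the
        canonical energy uses the upper triangle once)."""
        upper = np.triu(self.Q, k=1)
        return np.diag(np.diagonal(self.Q)) + (upper + upper.T) / 2.0

    def to_coo_text(self) -> str:
        """Plain-text COO triples ``u v coefficient`` (u == v rows are the
        linear terms), preceded by a JSON header line."""
        header = json.dumps(
            {"n": self.n, "labels": list(self.labels), "params": self.params}
        )
        lines = [f"# {header}"]
        for u in range(self.N):
            for v in range(u, self.N):
                if self.Q[u, v] != 0:
                    lines.append(f"{u} {v} {self.Q[u, v]:.17g}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IsingModel:
    """Spin model  E(s) = sum_u h_u s_u + sum_{u<v} J_uv s_u s_v + offset.

    Exactly equivalent to the QUBO it was derived from under the bijection
    x_u = (1 + s_u) / 2, offset included.
    """

    h: np.ndarray
    J: Mapping[tuple[int, int], float]
    offset: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        object.__setattr__(self, "h", h)
        for (u, v) in self.J:
            if not u < v:
                raise ValueError(f"coupling key ({u}, {v}) must satisfy u < v")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"s{u}" for u in range(len(h)))
            )

    @property
    def num_spins(self) -> int:
        return len(self.h)

    @property
    def N(self) -> int:
        return len(self.h)

    def to_text(self) -> str:
        lines = [f"# offset {self.offset:.17g}"]
        for u, hu in enumerate(self.h):
            if hu != 0:
                lines.append(f"h {u} {hu:.17g}")
        for (u, v), juv in sorted(self.J.items()):
            if juv != 0:
                lines.append(f"J {u} {v} {juv:.17g}")
        return "\n".join(lines) + "\n"


def tsp_to_qubo(
    tsp: TSPInstance, a: float = 0.0, b: float = 13.0, c: float = 13.0
) -> QuboModel:
    """Encode a directed TSP as a QUBO with reward/penalty structure.

    Four contribution classes, each added once per unordered variable pair
    into the upper triangle:

    1. assignment bias ``a`` on every diagonal entry;
    2. multi-location penalty ``b`` for every time slot p and node pair
       i < j (two nodes in the same slot);
    3. repetition penalty ``c`` for every node i and slot pair p < q (one
       node in two slots);
    4. path cost: for every directed edge (i, j) and slot p, the edge
       weight w_ij on the pair {(i, p), (j, (p+1) mod n)} — the modular
       wraparound makes the encoding a cycle, not a path.
    """
    n = tsp.n
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if b < 0 or c < 0:
        raise ValueError("penalties b and c must be nonnegative")
    N = n * n
    Q = np.zeros((N, N), dtype=float)

    for u in range(N):
        Q[u, u] += a
    for p in range(n):
        for i in range(n):
            for j in range(i + 1, n):
                Q[i * n + p, j * n + p] += b
    for i in range(n):
        for p in range(n):
            for q in range(p + 1, n):
                Q[i * n + p, i * n + q] += c
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for p in range(n):
                u = i * n + p
                v = j * n + ((p + 1) % n)
                lo, hi = (u, v) if u < v else (v, u)
                # for n = 2 opposite-direction edges land on the same
                # pair; contributions are summed
                Q[lo, hi] += tsp.weights[i, j]

    return QuboModel(Q=Q, n=n, params=(float(a), float(b), float(c)))


def sufficient_penalty(tsp: TSPInstance) -> float:
    """Theoretical penalty scale alpha = n * max |w_ij| guaranteeing that
    constraint violations cost more than any tour-cost gain.  Offered as a
    preset alternative to hand-tuned penalties."""
    return float(tsp.n * np.max(np.abs(tsp.weights)))


def interaction_count(qubo: QuboModel) -> int:
    """Number of nonzero strict-upper-triangle entries of Q.

    Equals 2 n^2 (n-1) for a TSP encoding with nonzero penalties and
    all-nonzero edge weights.
    """
    N = qubo.N
    upper = qubo.Q[np.triu_indices(N, k=1)]
    return int(np.count_nonzero(upper))


def _check_binary(x: Sequence[int], N: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (N,):
        raise ValueError(f"configuration must have length {N}, got {x.shape}")
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("configuration entries must be 0 or 1")
    return x.astype(float)


def qubo_energy(qubo: QuboModel, x: Sequence[int]) -> float:
    """y = sum_u Q[u][u] x_u + sum_{u<v} Q[u][v] x_u x_v."""
    xv = _check_binary(x, qubo.N)
    return float(xv @ qubo.Q @ xv)  # lower triangle is zero, so this is exact


def qubo_to_ising(qubo: QuboModel) -> IsingModel:
    """Exact substitution x_u = (1 + s_u) / 2.

    Every linear coefficient contributes half of itself to h and to the
    offset; every pairwise coefficient contributes a quarter of itself to
    J, to each of the two h entries, and to the offset.
    """
    N = qubo.N
    h = np.zeros(N)
    J: dict[tuple[int, int], float] = {}
    offset = 0.0
    for u in range(N):
        quu = qubo.Q[u, u]
        h[u] += quu / 2.0
        offset += quu / 2.0
    for u in range(N):
        for v in range(u + 1, N):
            quv = qubo.Q[u, v]
            if quv == 0:
                continue
            J[(u, v)] = quv / 4.0
            h[u] += quv / 4.0
            h[v] += quv / 4.0
            offset += quv / 4.0
    return IsingModel(h=h, J=J, offset=offset, labels=qubo.labels)


def ising_to_qubo(ising: IsingModel) -> QuboModel:
    """Inverse transform via s_u = 2 x_u - 1."""
    N = ising.N
    Q = np.zeros((N, N))
    const = float(ising.offset)
    for u, hu in enumerate(ising.h):
        Q[u, u] += 2.0 * hu
        const -= hu
    for (u, v), juv in ising.J.items():
        Q[u, v] += 4.0 * juv
        Q[u, u] -= 2.0 * juv
        Q[v, v] -= 2.0 * juv
        const += juv
    if abs(const) > 1e-12:
        raise ValueError(
            f"Ising model has residual constant {const}; "
            "QUBO form cannot represent it"
        )
    return QuboModel(Q=Q, labels=ising.labels)


def ising_energy(
    ising: IsingModel, s: Sequence[int], include_offset: bool = True
) -> float:
    """E = sum_u h_u s_u + sum_{u<v} J_uv s_u s_v (+ offset if flagged)."""
    sv = np.asarray(s)
    if sv.shape != (ising.N,):
        raise ValueError(f"spin vector must have length {ising.N}")
    if not np.all((sv == 1) | (sv == -1)):
        raise ValueError("spin entries must be -1 or +1")
    sv = sv.astype(float)
    energy = float(ising.h @ sv)
    for (u, v), juv in ising.J.items():
        energy += juv * sv[u] * sv[v]
    if include_offset:
        energy += ising.offset
    return energy
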