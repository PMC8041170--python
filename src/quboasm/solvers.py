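"""Classical ground-state solvers: exhaustive enumeration and simulated
annealing.

Enumeration is the exact reference for every other solver; simulated
annealing is the classical stand-in for a hardware annealer, sampling
low-energy spin configurations with single-spin-flip Metropolis updates.

Configuration/state-index convention used package-wide: variable u is bit
position u reading the configuration string left to right, so the integer
index of a configuration is ``sum(x[u] << (N - 1 - u))`` and the binary
string of the index equals the configuration written out in variable
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .qubo import IsingModel, QuboModel

__all__ = [
    "SampleRecord",
    "SampleSet",
    "ENUMERATION_GUARD_BITS",
    "solve_exact",
    "simulated_annealing",
]

ENUMERATION_GUARD_BITS = 24  # 2^24 = 16.7M states, still desk-scale
_CHUNK = 1 << 18
_ENERGY_DECIMALS = 9  # ties grouped after rounding to 1e-9


@dataclass(frozen=True)
class SampleRecord:
    configuration: tuple[int, ...]
    energy: float
    multiplicity: int = 1


@dataclass(frozen=True)
class SampleSet:
    """Solver output: records sorted ascending by energy, ties broken
    lexicographically by configuration.  ``convention`` states whether
    configurations are binary {0,1} or spin {-1,+1} vectors."""

    convention: Literal["binary", "spin"]
    records: tuple[SampleRecord, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(
                self.records,
                key=lambda r: (round(r.energy, _ENERGY_DECIMALS), r.configuration),
            )
        )
        object.__setattr__(self, "records", ordered)

    @property
    def best_energy(self) -> float:
        return self.records[0].energy

    def minima(self) -> list[SampleRecord]:
        """All records tied (to 1e-9) with the lowest energy."""
        best = round(self.records[0].energy, _ENERGY_DECIMALS)
        return [
            r for r in self.records if round(r.energy, _ENERGY_DECIMALS) == best
        ]

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "records": [
                ["".join(str(int(b)) for b in r.configuration)
                 if self.convention == "binary"
                 else "".join("+" if s > 0 else "-" for s in r.configuration),
                 r.energy, r.multiplicity]
                for r in self.records
            ],
            "metadata": self.metadata,
        }


def _bit_matrix(start: int, stop: int, N: int) -> np.ndarray:
    """Rows are the binary configurations of state indices [start, stop)."""
    idx = np.arange(start, stop, dtype=np.uint64)
    shifts = np.arange(N - 1, -1, -1, dtype=np.uint64)
    return ((idx[:, None] >> shifts) & np.uint64(1)).astype(np.float64)


def _dense_coupling(ising: IsingModel) -> np.ndarray:
    N = ising.N
    Jm = np.zeros((N, N))
    for (u, v), juv in ising.J.items():
        Jm[u, v] = juv
    return Jm


def _chunk_energies(model: QuboModel | IsingModel, start: int, stop: int) -> np.ndarray:
    N = model.N
    X = _bit_matrix(start, stop, N)
    if isinstance(model, QuboModel):
        diag = np.diagonal(model.Q)
        upper = np.triu(model.Q, k=1)
        return X @ diag + np.einsum("su,uv,sv->s", X, upper, X, optimize=True)
    S = 2.0 * X - 1.0  # bit b -> spin 2b-1, matching x = (1+s)/2
    Jm = _dense_coupling(model)
    return (
        S @ model.h
        + np.einsum("su,uv,sv->s", S, Jm, S, optimize=True)
        + model.offset
    )


def _config_from_index(index: int, N: int, spin: bool) -> tuple[int, ...]:
    bits = tuple((index >> (N - 1 - u)) & 1 for u in range(N))
    if spin:
        return tuple(2 * b - 1 for b in bits)
    return bits


def solve_exact(
    model: QuboModel | IsingModel,
    keep: Literal["minima", "all"] | int = "minima",
) -> SampleSet:
    """Enumerate every configuration of a QUBO or Ising model.

    ``keep`` selects what is returned: ``"minima"`` (all tied global
    minima — essential when the ground state is degenerate), an integer k
    (the k lowest-energy states), or ``"all"`` (the full spectrum, only
    for N <= 16).  Deterministic; Ising energies include the offset so
    QUBO and Ising representations of the same model agree exactly.
    """
    N = model.N
    if N > ENUMERATION_GUARD_BITS:
        raise ValueError(
            f"N={N} exceeds the exhaustive-enumeration guard of "
            f"{ENUMERATION_GUARD_BITS} variables (2^{N} states)"
        )
    spin = isinstance(model, IsingModel)
    total = 1 << N

    if keep == "all":
        if N > 16:
            raise ValueError("full-spectrum output limited to N <= 16")
        energies = _chunk_energies(model, 0, total)
        records = tuple(
            SampleRecord(_config_from_index(i, N, spin), float(energies[i]))
            for i in range(total)
        )
        return SampleSet(
            convention="spin" if spin else "binary",
            records=records,
            metadata={"solver": "exact", "keep": "all", "states": total},
        )

    k = None if keep == "minima" else int(keep)
    if k is not None and k < 1:
        raise ValueError("keep must be 'minima', 'all', or a positive integer")

    # single pass keeping candidate (energy, index) pairs per chunk
    best: list[tuple[float, int]] = []
    tol = 10.0 ** (-_ENERGY_DECIMALS)
    for start in range(0, total, _CHUNK):
        stop = min(start + _CHUNK, total)
        energies = _chunk_energies(model, start, stop)
        if k is None:
            emin = energies.min()
            running = best[0][0] if best else np.inf
            if emin < running - tol:
                best = []
            cut = min(running, emin) + tol
            for i in np.flatnonzero(energies <= cut):
                best.append((float(energies[i]), start + int(i)))
            best = [p for p in best if p[0] <= min(e for e, _ in best) + tol]
        else:
            for i in np.argpartition(energies, min(k, len(energies)) - 1)[:k]:
                best.append((float(energies[i]), start + int(i)))
            best.sort()
            best = best[:k]

    records = tuple(
        SampleRecord(_config_from_index(idx, N, spin), e) for e, idx in best
    )
    return SampleSet(
        convention="spin" if spin else "binary",
        records=records,
        metadata={"solver": "exact", "keep": keep, "states": total},
    )


def simulated_annealing(
    ising: IsingModel,
    n_samples: int = 1000,
    sweeps: int = 1000,
    beta_schedule: tuple[float, float, str] = (0.1, 10.0, "geometric"),
    seed: int | None = None,
) -> SampleSet:
    """Sample low-energy spin states with single-spin-flip Metropolis.

    Runs ``n_samples`` independent anneals from uniform random spins, each
    doing ``sweeps`` full sweeps while the inverse temperature follows the
    given schedule.  Identical final configurations are aggregated into
    one record with a multiplicity.  Fully deterministic given ``seed``.
    """
    if n_samples < 1 or sweeps < 1:
        raise ValueError("n_samples and sweeps must be >= 1")
    b0, b1, kind = beta_schedule
    if not (np.isfinite(b0) and np.isfinite(b1)):
        raise ValueError("beta schedule endpoints must be finite")
    if kind == "geometric":
        if b0 <= 0 or b1 <= 0:
            raise ValueError("geometric schedule requires positive endpoints")
        betas = np.geomspace(b0, b1, sweeps)
    elif kind == "linear":
        betas = np.linspace(b0, b1, sweeps)
    else:
        raise ValueError(f"unknown schedule kind {kind!r} (geometric|linear)")

    N = ising.N
    rng = np.random.default_rng(seed)
    S = rng.choice([-1.0, 1.0], size=(n_samples, N))
    Jm = _dense_coupling(ising)
    Jsym = Jm + Jm.T  # row u gives each pair's coupling once for spin u
    h = ising.h

    for beta in betas:
        for u in range(N):
            local = h[u] + S @ Jsym[:, u]
            dE = -2.0 * S[:, u] * local
            accept = (dE <= 0) | (
                rng.random(n_samples) < np.exp(np.clip(-beta * dE, None, 0.0))
            )
            S[accept, u] *= -1.0

    energies = (
        S @ h + 0.5 * np.einsum("su,uv,sv->s", S, Jsym, S, optimize=True)
        + ising.offset
    )
    counter: dict[tuple[int, ...], tuple[float, int]] = {}
    for row, e in zip(S.astype(int), energies):
        key = tuple(row)
        prev = counter.get(key)
        counter[key] = (float(e), (prev[1] + 1) if prev else 1)
    records = tuple(
        SampleRecord(cfg, e, mult) for cfg, (e, mult) in counter.items()
    )
    return SampleSet(
        convention="spin",
        records=records,
        metadata={
            "solver": "simulated_annealing",
            "seed": seed,
            "n_samples": n_samples,
            "sweeps": sweeps,
            "beta_schedule": list(beta_schedule),
        },
    )
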