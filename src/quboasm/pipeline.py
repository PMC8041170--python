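"""Decode solver configurations into tours and stitch reads into sequence.

The end-to-end chain is: reads -> overlap TSP -> QUBO (-> Ising) ->
solver -> decoded tour(s) -> stitched assembly.  Invalid solver outputs
(non-permutation assignments) are reported with a diagnosis, never
silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .qubo import qubo_to_ising, tsp_to_qubo
from .reads import ReadSet, generate_circular_reads, pairwise_overlap, read_fasta, reads_to_tsp
from .solvers import simulated_annealing, solve_exact
from .tsp import Tour, rotations

__all__ = [
    "DecodeResult",
    "AssemblyResult",
    "decode_assignment",
    "encode_tour",
    "stitch",
    "reduce_circular",
    "run_pipeline",
]


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of interpreting a solver configuration as a node/slot
    assignment: a tour when the assignment is a permutation matrix,
    otherwise a diagnosis of what went wrong."""

    valid: bool
    tour: Tour | None
    problems: tuple[str, ...] = ()


def decode_assignment(configuration: Sequence[int], n: int) -> DecodeResult:
    """Interpret a length-n^2 binary or spin vector as a tour.

    Variable i*n + p set means node i is visited at slot p.  Spin vectors
    (any entry equal to -1) are mapped through x = (1 + s) / 2.  Returns
    the slot-ordered tour iff the assignment matrix has exactly one 1 per
    row and per column; otherwise every violation is listed.
    """
    x = np.asarray(configuration)
    if x.shape != (n * n,):
        raise ValueError(
            f"configuration must have length {n * n}, got {x.shape}"
        )
    if np.any(x == -1):
        if not np.all((x == -1) | (x == 1)):
            raise ValueError("spin configuration entries must be -1 or +1")
        x = (1 + x) // 2
    elif not np.all((x == 0) | (x == 1)):
        raise ValueError("binary configuration entries must be 0 or 1")
    M = x.reshape(n, n)  # rows: nodes, columns: time slots

    problems: list[str] = []
    for i, row in enumerate(M):
        if row.sum() == 0:
            problems.append(f"node {i} unassigned")
        elif row.sum() > 1:
            problems.append(f"node {i} assigned to multiple slots")
    for p, col in enumerate(M.T):
        if col.sum() == 0:
            problems.append(f"slot {p} empty")
        elif col.sum() > 1:
            problems.append(f"slot {p} double-booked")
    if problems:
        return DecodeResult(valid=False, tour=None, problems=tuple(problems))
    order = tuple(int(np.argmax(M[:, p])) for p in range(n))
    return DecodeResult(valid=True, tour=Tour(order))


def encode_tour(tour: Tour) -> tuple[int, ...]:
    """Inverse of decode: the length-n^2 binary assignment of a tour."""
    n = len(tour)
    x = [0] * (n * n)
    for p, node in enumerate(tour.order):
        x[node * n + p] = 1
    return tuple(x)


@dataclass(frozen=True)
class AssemblyResult:
    """A stitched linear assembly.

    ``assembled_length == sum(read lengths) - total_overlap`` where
    ``total_overlap`` covers the n-1 internal junctions; the closing
    (cycle) overlap is reported separately and not trimmed.
    """

    tour: Tour
    sequence: str
    total_overlap: int
    closing_overlap: int
    assembled_length: int
    valid: bool
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tour": list(self.tour.order),
            "sequence": self.sequence,
            "total_overlap": self.total_overlap,
            "closing_overlap": self.closing_overlap,
            "assembled_length": self.assembled_length,
            "valid": self.valid,
            "provenance": self.provenance,
        }


def stitch(
    readset: ReadSet, tour: Tour, provenance: dict | None = None
) -> AssemblyResult:
    """Concatenate reads in tour order, trimming each exact junction overlap.

    The output is linear, starting at the tour's first read; the overlap
    that would close the cycle is measured but kept untrimmed.
    """
    n = len(readset)
    if len(tour) != n:
        raise ValueError(f"tour length {len(tour)} != read count {n}")
    order = tour.order
    sequence = readset[order[0]]
    total_overlap = 0
    for k in range(1, n):
        prev, curr = readset[order[k - 1]], readset[order[k]]
        ov = pairwise_overlap(prev, curr)
        total_overlap += ov
        sequence += curr[ov:]
    closing = pairwise_overlap(readset[order[-1]], readset[order[0]]) if n > 1 else 0
    return AssemblyResult(
        tour=tour,
        sequence=sequence,
        total_overlap=total_overlap,
        closing_overlap=closing,
        assembled_length=len(sequence),
        valid=True,
        provenance=provenance or {},
    )


def reduce_circular(result: AssemblyResult) -> str:
    """Circular reduction: trim the closing overlap off the linear stitch,
    recovering one period of a circular template."""
    if result.closing_overlap == 0:
        return result.sequence
    return result.sequence[: -result.closing_overlap]


def _load_reads(
    reads: Sequence[str] | None = None,
    fasta: str | None = None,
    genome: str | None = None,
    offsets: Sequence[int] | None = None,
    read_length: int | None = None,
) -> ReadSet:
    sources = sum(x is not None for x in (reads, fasta, genome))
    if sources != 1:
        raise ValueError("provide exactly one of reads, fasta or genome")
    if reads is not None:
        return ReadSet.from_strings(reads)
    if fasta is not None:
        return read_fasta(fasta)
    if offsets is None or read_length is None:
        raise ValueError("genome input requires offsets and read_length")
    return generate_circular_reads(genome, offsets, read_length)


def run_pipeline(
    reads: Sequence[str] | None = None,
    fasta: str | None = None,
    genome: str | None = None,
    offsets: Sequence[int] | None = None,
    read_length: int | None = None,
    a: float = 0.0,
    b: float = 13.0,
    c: float = 13.0,
    solver: Literal["exact", "sa", "qaoa"] = "exact",
    solver_params: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full chain and return a JSON-serializable report.

    The report carries the overlap matrix, encoding summaries, raw solver
    output, the decode of every co-minimal (or top-probability)
    configuration, and a stitched assembly for each valid tour.  The
    lexicographically smallest valid tour is marked canonical.
    """
    solver_params = dict(solver_params or {})
    readset = _load_reads(reads, fasta, genome, offsets, read_length)
    try:
        tsp = reads_to_tsp(readset)
    except ValueError as exc:
        raise ValueError(f"stage reads_to_tsp: {exc}") from exc
    qubo = tsp_to_qubo(tsp, a=a, b=b, c=c)
    ising = qubo_to_ising(qubo)

    report: dict = {
        "reads": readset.to_dict(),
        "overlap_matrix": (-tsp.weights).astype(int).tolist(),
        "tsp_weights": tsp.weights.tolist(),
        "qubo": {
            "n": qubo.n,
            "num_variables": qubo.N,
            "params": qubo.params,
            "labels": list(qubo.labels),
        },
        "ising": {
            "offset": ising.offset,
            "num_biases": int(np.count_nonzero(ising.h)),
            "num_couplings": len(ising.J),
        },
        "solver": {"name": solver, "seed": seed, "params": solver_params},
    }

    configs: list[tuple[tuple[int, ...], dict]] = []
    if solver == "exact":
        sampleset = solve_exact(qubo, keep="minima")
        report["sampleset"] = sampleset.to_dict()
        for rec in sampleset.minima():
            configs.append((rec.configuration, {"energy": rec.energy}))
    elif solver == "sa":
        sampleset = simulated_annealing(ising, seed=seed, **solver_params)
        report["sampleset"] = sampleset.to_dict()
        for rec in sampleset.minima():
            configs.append((rec.configuration, {"energy": rec.energy}))
    elif solver == "qaoa":
        from .qaoa import run_qaoa

        result = run_qaoa(tsp, seed=seed, **solver_params)
        report["qaoa"] = result.to_dict()
        for bitstring, prob in result.probabilities.items():
            configs.append(
                (tuple(int(ch) for ch in bitstring), {"probability": prob})
            )
    else:
        raise ValueError(f"unknown solver {solver!r} (exact|sa|qaoa)")

    decoded_entries = []
    assemblies = []
    valid_tours: list[Tour] = []
    for config, extra in configs:
        dec = decode_assignment(config, tsp.n)
        entry = {
            "configuration": list(int(v) for v in config),
            "valid": dec.valid,
            "tour": list(dec.tour.order) if dec.valid else None,
            "problems": list(dec.problems),
            **extra,
        }
        decoded_entries.append(entry)
        if dec.valid:
            valid_tours.append(dec.tour)
            assemblies.append(
                stitch(
                    readset,
                    dec.tour,
                    provenance={"solver": solver, "seed": seed, **extra},
                )
            )
    report["decoded"] = decoded_entries
    report["assemblies"] = [asm.to_dict() for asm in assemblies]
    if valid_tours:
        canonical = min(t.order for t in valid_tours)
        report["canonical_tour"] = list(canonical)
        canonical_asm = next(
            asm for asm in assemblies if asm.tour.order == canonical
        )
        report["canonical_sequence"] = canonical_asm.sequence
        report["canonical_circular_sequence"] = reduce_circular(canonical_asm)
    return report
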