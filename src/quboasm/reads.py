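"""DNA read handling and exact suffix-prefix overlap graphs.

Reads are plain uppercase A/C/G/T strings.  The pairwise overlap of an
ordered read pair (a, b) is the length of the longest proper suffix of
``a`` that is also a prefix of ``b``; negating these overlaps yields the
edge weights of a directed complete graph, i.e. a traveling-salesman
instance whose minimum-weight Hamiltonian cycle orders the reads for
assembly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

__all__ = [
    "DNA_ALPHABET",
    "ReadSet",
    "TSPInstance",
    "ReadValidationError",
    "FastaParseError",
    "read_fasta",
    "generate_circular_reads",
    "pairwise_overlap",
    "reads_to_tsp",
]


class ReadValidationError(ValueError):
    """A read contains characters outside {A, C, G, T} or is empty."""


class FastaParseError(ValueError):
    """The input file is not well-formed FASTA."""


def _validate_read(read: str, label: str) -> str:
    """Uppercase ``read`` and reject anything outside the strict alphabet.

    IUPAC ambiguity codes are rejected rather than normalized: exact-match
    overlap scoring is meaningless on ambiguous bases.
    """
    if not read:
        raise ReadValidationError(f"{label}: read is empty")
    upper = read.upper()
    for pos, ch in enumerate(upper):
        if ch not in DNA_ALPHABET:
            raise ReadValidationError(
                f"{label}: invalid symbol {ch!r} at position {pos} "
                "(only A, C, G, T are accepted)"
            )
    return upper


@dataclass(frozen=True)
class ReadSet:
    """Ordered, deduplicated collection of validated DNA reads.

    Index ``i`` in the read set is node ``i`` in every downstream graph,
    encoding and solver output.  Duplicate reads are removed on
    construction (first occurrence kept) and recorded in
    ``dropped_duplicates``.
    """

    reads: tuple[str, ...]
    labels: tuple[str, ...]
    dropped_duplicates: tuple[str, ...] = ()

    @classmethod
    def from_strings(
        cls, reads: Sequence[str], labels: Sequence[str] | None = None
    ) -> "ReadSet":
        if labels is None:
            labels = [f"read {i}" for i in range(len(reads))]
        if len(labels) != len(reads):
            raise ValueError("labels and reads must have equal length")
        seen: dict[str, int] = {}
        kept_reads: list[str] = []
        kept_labels: list[str] = []
        dropped: list[str] = []
        for read, label in zip(reads, labels):
            validated = _validate_read(read, str(label))
            if validated in seen:
                dropped.append(str(label))
                continue
            seen[validated] = len(kept_reads)
            kept_reads.append(validated)
            kept_labels.append(str(label))
        return cls(tuple(kept_reads), tuple(kept_labels), tuple(dropped))

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[str]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> str:
        return self.reads[i]

    def to_dict(self) -> dict:
        return {
            "reads": list(self.reads),
            "labels": list(self.labels),
            "dropped_duplicates": list(self.dropped_duplicates),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class TSPInstance:
    """Directed complete graph over reads; ``weights[i, j]`` is the cost
    of the edge i -> j.  Built from reads, weights are negated overlaps
    (hence <= 0) and generally asymmetric.  Diagonal entries are unused
    and fixed at 0.
    """

    n: int
    weights: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.n, self.n):
            raise ValueError(f"weights must be {self.n}x{self.n}, got {w.shape}")
        if not np.all(np.diagonal(w) == 0):
            raise ValueError("diagonal entries must be 0")
        object.__setattr__(self, "weights", w)
        if len(self.labels) != self.n:
            raise ValueError("labels length must equal n")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "labels": list(self.labels),
            "weights": self.weights.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def read_fasta(path: str | Path) -> ReadSet:
    """Parse a (multi-record, wrapped or unwrapped) FASTA file into a ReadSet.

    Records are kept in file order, uppercased and validated; duplicate
    sequences are dropped (first kept) and logged on the result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # SeqIO is forgiving about leading junk; do a strict pre-scan so a
    # malformed file fails loudly with a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header "
                    f"starting with '>', got {stripped[:30]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path}: file contains no FASTA records")
    reads: list[str] = []
    labels: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        label = record.id if record.id else f"read {len(reads)}"
        reads.append(str(record.seq))
        labels.append(label)
    if not reads:
        raise FastaParseError(f"{path}: file contains no FASTA records")
    return ReadSet.from_strings(reads, labels)


def generate_circular_reads(
    genome: str, offsets: Sequence[int], read_length: int
) -> ReadSet:
    """Extract fixed-length windows from a circular genome.

    Read ``k`` is the window of ``read_length`` characters starting at
    ``offsets[k]``, indices taken modulo the genome length, so windows may
    wrap around the origin.  The result is deduplicated like any ReadSet.
    """
    genome = _validate_read(genome, "genome")
    if len(offsets) == 0:
        raise ValueError("offsets must be a nonempty list")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    size = len(genome)
    for off in offsets:
        if not 0 <= off < size:
            raise ValueError(f"offset {off} outside [0, {size})")
    reads = [
        "".join(genome[(off + k) % size] for k in range(read_length))
        for off in offsets
    ]
    labels = [f"read {i}" for i in range(len(reads))]
    return ReadSet.from_strings(reads, labels)


def pairwise_overlap(a: str, b: str) -> int:
    """Length of the longest proper suffix of ``a`` equal to a prefix of ``b``.

    The overlap k is capped at min(|a|, |b|) - 1 so a read never fully
    contains the match; k = 0 means no overlap.
    """
    for k in range(min(len(a), len(b)) - 1, 0, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def reads_to_tsp(readset: ReadSet) -> TSPInstance:
    """Build the directed TSP instance whose edge weight i -> j is the
    negated pairwise overlap of read i onto read j."""
    n = len(readset)
    if n < 2:
        raise ValueError("at least 2 reads are required to build a TSP instance")
    weights = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            if i != j:
                weights[i, j] = -pairwise_overlap(readset[i], readset[j])
    return TSPInstance(n=n, weights=weights, labels=readset.labels)
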