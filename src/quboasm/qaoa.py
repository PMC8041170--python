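"""QAOA on a dense statevector simulator.

The cost Hamiltonian is a weighted sum of Pauli products (here only I/Z,
so it is diagonal) built from the TSP instance in four groups:

* HC1 — a uniform +w bias term ``w * Z_q`` on every qubit;
* HC2 — co-location penalties, one group per time slot and node pair:
  ``-w/2 Z_a - w/2 Z_b + w/2 Z_a Z_b``;
* HC3 — repetition penalties, identical structure per node and slot pair;
* HC4 — path costs, ``-d/4 Z_a - d/4 Z_b + d/4 Z_a Z_b`` for each
  directed edge with weight d placed on consecutive (modular) slots.

The ansatz alternates cost layers (RZ and CNOT-RZ-CNOT sandwiches, angles
scaled by gamma) with transverse mixer layers (RX on every qubit, angles
scaled by beta), applied to an equal superposition.  Angle convention:
RZ(t) = exp(-i t Z / 2), RX(t) = exp(-i t X / 2); a term coeff * Z... is
compiled with t = 2 * coeff * gamma so one cost block implements
exp(-i gamma H_C) exactly up to global phase.

Bit/eigenvalue convention: bit 0 of a basis state maps to Z eigenvalue
+1, bit 1 to -1; qubit q is bit position q (left to right), matching the
configuration-index convention of the classical solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .reads import TSPInstance

__all__ = [
    "PauliHamiltonian",
    "Gate",
    "ParamCircuit",
    "QaoaResult",
    "STATEVECTOR_GUARD_QUBITS",
    "SUPPORTED_OPTIMIZERS",
    "build_cost_hamiltonian",
    "diagonal_energies",
    "build_ansatz",
    "simulate_statevector",
    "expectation",
    "sample_counts",
    "optimize_angles",
    "run_qaoa",
]

STATEVECTOR_GUARD_QUBITS = 20
SUPPORTED_OPTIMIZERS = ("Nelder-Mead", "Powell", "BFGS")
DEFAULT_HC1_WEIGHT = 100000.0


@dataclass(frozen=True)
class PauliHamiltonian:
    """Weighted sum of Pauli product words; only nonzero terms stored.

    ``terms`` maps each length-N word over {I, X, Y, Z} to its real
    coefficient; duplicate words are merged by summing on construction.
    """

    n_qubits: int
    terms: tuple[tuple[float, str], ...]

    @classmethod
    def from_terms(
        cls, n_qubits: int, terms: Sequence[tuple[float, str]]
    ) -> "PauliHamiltonian":
        merged: dict[str, float] = {}
        for coeff, word in terms:
            if len(word) != n_qubits:
                raise ValueError(
                    f"word {word!r} has length {len(word)}, expected {n_qubits}"
                )
            if any(ch not in "IXYZ" for ch in word):
                raise ValueError(f"invalid Pauli word {word!r}")
            merged[word] = merged.get(word, 0.0) + float(coeff)
        kept = tuple(
            (coeff, word) for word, coeff in merged.items() if coeff != 0.0
        )
        return cls(n_qubits=n_qubits, terms=kept)

    @property
    def is_diagonal(self) -> bool:
        return all(set(word) <= {"I", "Z"} for _, word in self.terms)

    def to_text(self) -> str:
        return "\n".join(f"{c:.17g} {w}" for c, w in self.terms) + "\n"


def _z_word(n_qubits: int, qubits: Sequence[int]) -> str:
    word = ["I"] * n_qubits
    for q in qubits:
        word[q] = "Z"
    return "".join(word)


def build_cost_hamiltonian(
    tsp: TSPInstance, w: float = DEFAULT_HC1_WEIGHT
) -> PauliHamiltonian:
    """Assemble HC = HC1 + HC2 + HC3 + HC4 over N = n^2 qubits.

    Qubit i*n + r represents "node i at time slot r".  Constant (all-I)
    contributions are omitted by the printed sums; they only shift the
    spectrum.  Duplicate words are merged.
    """
    n = tsp.n
    N = n * n
    if N > STATEVECTOR_GUARD_QUBITS:
        raise ValueError(
            f"N={N} qubits exceeds the statevector guard "
            f"({STATEVECTOR_GUARD_QUBITS})"
        )
    terms: list[tuple[float, str]] = []

    # HC1: uniform positive bias on every qubit
    for q in range(N):
        terms.append((w, _z_word(N, [q])))

    # HC2: two nodes in the same time slot
    for r in range(n):
        for i in range(1, n):
            for j in range(i):
                a, b = i * n + r, j * n + r
                terms.append((-w / 2, _z_word(N, [a])))
                terms.append((-w / 2, _z_word(N, [b])))
                terms.append((w / 2, _z_word(N, [a, b])))

    # HC3: one node in two time slots
    for i in range(n):
        for r in range(1, n):
            for s in range(r):
                a, b = i * n + r, i * n + s
                terms.append((-w / 2, _z_word(N, [a])))
                terms.append((-w / 2, _z_word(N, [b])))
                terms.append((w / 2, _z_word(N, [a, b])))

    # HC4: directed edge costs on consecutive (modular) slots
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = tsp.weights[i, j]
            for r in range(n):
                s = (r + 1) % n
                a, b = i * n + r, j * n + s
                terms.append((-d / 4, _z_word(N, [a])))
                terms.append((-d / 4, _z_word(N, [b])))
                terms.append((d / 4, _z_word(N, [a, b])))

    return PauliHamiltonian.from_terms(N, terms)


def diagonal_energies(ham: PauliHamiltonian) -> np.ndarray:
    """Eigenvalue of each of the 2^N basis states under a diagonal (I/Z)
    Hamiltonian, in state-index order."""
    if not ham.is_diagonal:
        raise ValueError("Hamiltonian contains non-diagonal (X/Y) words")
    N = ham.n_qubits
    idx = np.arange(1 << N, dtype=np.uint64)
    energies = np.zeros(1 << N)
    for coeff, word in ham.terms:
        mask = np.uint64(0)
        for q, ch in enumerate(word):
            if ch == "Z":
                mask |= np.uint64(1 << (N - 1 - q))
        parity = np.bitwise_count(idx & mask) & np.uint64(1)
        energies += coeff * (1.0 - 2.0 * parity.astype(np.float64))
    return energies


@dataclass(frozen=True)
class Gate:
    """One circuit gate.  Parameterized gates reference a (kind, step)
    angle slot; the applied angle is ``scale * parameter``."""

    name: Literal["H", "RZ", "RX", "CNOT"]
    qubits: tuple[int, ...]
    scale: float | None = None
    slot: tuple[Literal["gamma", "beta"], int] | None = None


@dataclass(frozen=True)
class ParamCircuit:
    """Alternating QAOA ansatz: fixed prologue, then per step one cost
    layer (gamma-parameterized) and one mixer layer (beta-parameterized)."""

    n_qubits: int
    prologue: tuple[Gate, ...]
    blocks: tuple[tuple[tuple[Gate, ...], tuple[Gate, ...]], ...]

    @property
    def steps(self) -> int:
        return len(self.blocks)


def build_ansatz(ham: PauliHamiltonian, steps: int = 1) -> ParamCircuit:
    """Compile a diagonal Hamiltonian into the alternating ansatz.

    Prologue: Hadamard on every qubit (equal superposition reference
    state).  Per step: each single-Z term on q becomes RZ(2*coeff*gamma)
    on q; each ZZ term on (a, b) becomes CNOT(a,b), RZ(2*coeff*gamma) on
    b, CNOT(a,b); then the mixer applies RX(2*beta) to every qubit.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not ham.is_diagonal:
        raise ValueError("only diagonal (I/Z) Hamiltonians are supported")
    N = ham.n_qubits
    prologue = tuple(Gate("H", (q,)) for q in range(N))
    blocks = []
    for step in range(steps):
        cost: list[Gate] = []
        for coeff, word in ham.terms:
            zs = tuple(q for q, ch in enumerate(word) if ch == "Z")
            if len(zs) == 0:
                continue  # all-I term is a global phase
            if len(zs) == 1:
                cost.append(Gate("RZ", zs, 2.0 * coeff, ("gamma", step)))
            elif len(zs) == 2:
                a, b = zs
                cost.append(Gate("CNOT", (a, b)))
                cost.append(Gate("RZ", (b,), 2.0 * coeff, ("gamma", step)))
                cost.append(Gate("CNOT", (a, b)))
            else:
                raise ValueError(
                    "terms with more than two Z factors are not compiled"
                )
        mixer = tuple(
            Gate("RX", (q,), 2.0, ("beta", step)) for q in range(N)
        )
        blocks.append((tuple(cost), mixer))
    return ParamCircuit(n_qubits=N, prologue=prologue, blocks=tuple(blocks))


def _apply_gate(psi: np.ndarray, gate: Gate, angle: float | None) -> None:
    """Apply one gate in place to the (2,)*N state tensor."""
    if gate.name == "H":
        (q,) = gate.qubits
        v = np.moveaxis(psi, q, 0)
        s = 1.0 / np.sqrt(2.0)
        new0 = s * (v[0] + v[1])
        new1 = s * (v[0] - v[1])
        v[0], v[1] = new0, new1
    elif gate.name == "RZ":
        (q,) = gate.qubits
        v = np.moveaxis(psi, q, 0)
        v[0] *= np.exp(-0.5j * angle)
        v[1] *= np.exp(0.5j * angle)
    elif gate.name == "RX":
        (q,) = gate.qubits
        v = np.moveaxis(psi, q, 0)
        c, s = np.cos(angle / 2.0), np.sin(angle / 2.0)
        new0 = c * v[0] - 1j * s * v[1]
        new1 = -1j * s * v[0] + c * v[1]
        v[0], v[1] = new0, new1
    elif gate.name == "CNOT":
        a, b = gate.qubits
        v = np.moveaxis(psi, (a, b), (0, 1))
        tmp = v[1, 0].copy()
        v[1, 0] = v[1, 1]
        v[1, 1] = tmp
    else:  # pragma: no cover
        raise ValueError(f"unknown gate {gate.name!r}")


def simulate_statevector(
    circuit: ParamCircuit,
    gammas: Sequence[float],
    betas: Sequence[float],
) -> np.ndarray:
    """Dense statevector after applying the ansatz at the given angles.

    Returns the 2^N complex amplitudes in state-index order (qubit 0 is
    the leftmost / most significant bit).
    """
    N = circuit.n_qubits
    if N > STATEVECTOR_GUARD_QUBITS:
        raise ValueError(f"N={N} exceeds statevector guard")
    if len(gammas) != circuit.steps or len(betas) != circuit.steps:
        raise ValueError(
            f"expected {circuit.steps} gamma and beta values, got "
            f"{len(gammas)}/{len(betas)}"
        )
    psi = np.zeros((2,) * N, dtype=np.complex128)
    psi[(0,) * N] = 1.0
    params = {"gamma": list(gammas), "beta": list(betas)}
    for gate in circuit.prologue:
        _apply_gate(psi, gate, None)
    for cost, mixer in circuit.blocks:
        for gate in cost + mixer:
            angle = None
            if gate.slot is not None:
                kind, step = gate.slot
                angle = gate.scale * params[kind][step]
            _apply_gate(psi, gate, angle)
    return psi.reshape(-1)


def expectation(state: np.ndarray, ham: PauliHamiltonian) -> float:
    """<state| H |state> for a diagonal Hamiltonian."""
    probs = np.abs(state) ** 2
    norm = probs.sum()
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"state norm^2 = {norm} deviates from 1 beyond 1e-6")
    return float(probs @ diagonal_energies(ham))


def sample_counts(
    state: np.ndarray, shots: int, seed: int | None = None
) -> dict[str, float]:
    """Measurement statistics of a statevector in the computational basis.

    ``shots == 0`` bypasses sampling and returns the exact probability of
    every nonzero-probability basis state; otherwise a seeded multinomial
    draw returns integer counts.
    """
    if shots < 0:
        raise ValueError("shots must be >= 0")
    probs = np.abs(state) ** 2
    N = int(np.log2(len(probs)))
    if shots == 0:
        return {
            format(i, f"0{N}b"): float(p)
            for i, p in enumerate(probs)
            if p > 0
        }
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(shots, probs / probs.sum())
    return {
        format(i, f"0{N}b"): int(c) for i, c in enumerate(counts) if c > 0
    }


@dataclass(frozen=True)
class QaoaResult:
    gammas: tuple[float, ...]
    betas: tuple[float, ...]
    best_expectation: float
    trace: tuple[float, ...]  # best-so-far expectation per evaluation
    probabilities: dict[str, float]  # top-k basis states of the best state
    decoded: tuple[dict, ...]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gammas": list(self.gammas),
            "betas": list(self.betas),
            "best_expectation": self.best_expectation,
            "trace": list(self.trace),
            "probabilities": self.probabilities,
            "decoded": list(self.decoded),
            "metadata": self.metadata,
        }


def optimize_angles(
    ham: PauliHamiltonian,
    steps: int = 1,
    optimizer: str = "Nelder-Mead",
    max_iter: int = 200,
    restarts: int = 40,
    seed: int | None = None,
    init: Literal["random", "given"] = "random",
    initial_angles: Sequence[float] | None = None,
    top_k: int = 10,
) -> QaoaResult:
    """Variational loop: minimize the ansatz expectation over (gamma, beta).

    Each restart draws initial angles uniformly in [0, 2*pi) (or uses the
    supplied angles when ``init='given'``) and runs the chosen
    gradient-free SciPy optimizer.  The best-over-restarts angles, a
    monotone best-so-far convergence trace and the top-k basis-state
    probabilities of the optimized state are returned.
    """
    if optimizer not in SUPPORTED_OPTIMIZERS:
        raise ValueError(
            f"unknown optimizer {optimizer!r}; supported: "
            + ", ".join(SUPPORTED_OPTIMIZERS)
        )
    if init == "given" and initial_angles is None:
        raise ValueError("init='given' requires initial_angles")
    circuit = build_ansatz(ham, steps)
    energies = diagonal_energies(ham)  # reused across evaluations

    trace: list[float] = []
    best = {"value": np.inf, "params": None}

    def objective(theta: np.ndarray) -> float:
        state = simulate_statevector(circuit, theta[:steps], theta[steps:])
        value = float((np.abs(state) ** 2) @ energies)
        if value < best["value"]:
            best["value"] = value
            best["params"] = np.array(theta)
        trace.append(best["value"])
        return value

    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        if init == "given":
            theta0 = np.asarray(initial_angles, dtype=float)
            if theta0.shape != (2 * steps,):
                raise ValueError(f"initial_angles must have length {2 * steps}")
        else:
            theta0 = rng.uniform(0.0, 2.0 * np.pi, size=2 * steps)
        minimize(
            objective,
            theta0,
            method=optimizer,
            options={"maxiter": max_iter},
        )

    theta = best["params"]
    state = simulate_statevector(circuit, theta[:steps], theta[steps:])
    probs = np.abs(state) ** 2
    order = np.argsort(probs)[::-1][:top_k]
    N = ham.n_qubits
    prob_map = {format(int(i), f"0{N}b"): float(probs[i]) for i in order}

    return QaoaResult(
        gammas=tuple(theta[:steps]),
        betas=tuple(theta[steps:]),
        best_expectation=best["value"],
        trace=tuple(trace),
        probabilities=prob_map,
        decoded=(),
        metadata={
            "optimizer": optimizer,
            "max_iter": max_iter,
            "restarts": restarts,
            "seed": seed,
            "steps": steps,
            "evaluations": len(trace),
        },
    )


def run_qaoa(
    tsp: TSPInstance,
    steps: int = 1,
    w: float = DEFAULT_HC1_WEIGHT,
    optimizer: str = "Nelder-Mead",
    max_iter: int = 200,
    restarts: int = 40,
    seed: int | None = None,
    init: Literal["random", "given"] = "random",
    initial_angles: Sequence[float] | None = None,
    top_k: int = 10,
) -> QaoaResult:
    """End-to-end QAOA on a TSP instance: build the cost Hamiltonian,
    compile the ansatz, optimize the angles and decode the top basis
    states into tours (or diagnosed invalid assignments)."""
    from .pipeline import decode_assignment  # local import avoids a cycle

    ham = build_cost_hamiltonian(tsp, w=w)
    result = optimize_angles(
        ham,
        steps=steps,
        optimizer=optimizer,
        max_iter=max_iter,
        restarts=restarts,
        seed=seed,
        init=init,
        initial_angles=initial_angles,
        top_k=top_k,
    )
    decoded = []
    for bitstring, prob in result.probabilities.items():
        config = tuple(int(b) for b in bitstring)
        dec = decode_assignment(config, tsp.n)
        decoded.append(
            {
                "bitstring": bitstring,
                "probability": prob,
                "valid": dec.valid,
                "tour": list(dec.tour.order) if dec.valid else None,
                "problems": list(dec.problems),
            }
        )
    return QaoaResult(
        gammas=result.gammas,
        betas=result.betas,
        best_expectation=result.best_expectation,
        trace=result.trace,
        probabilities=result.probabilities,
        decoded=tuple(decoded),
        metadata={**result.metadata, "hc1_weight": w, "n": tsp.n},
    )
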