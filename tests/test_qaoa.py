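import numpy as np
import pytest

from quboasm import (
    PauliHamiltonian,
    build_ansatz,
    build_cost_hamiltonian,
    diagonal_energies,
    expectation,
    run_qaoa,
    sample_counts,
    simulate_statevector,
)
from quboasm.qaoa import Gate, ParamCircuit, optimize_angles

from conftest import TYPE_A_ASSIGNMENTS, random_tsp

# ---------------------------------------------------------------------------
# independent oracles


def kron_oracle(circuit: ParamCircuit, gammas, betas) -> np.ndarray:
    """Gate-by-gate dense-matrix simulation via explicit Kronecker products."""
    N = circuit.n_qubits
    I2 = np.eye(2, dtype=complex)
    H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)

    def one_qubit(U, q):
        ops = [I2] * N
        ops[q] = U
        out = ops[0]
        for op in ops[1:]:
            out = np.kron(out, op)
        return out

    def cnot(a, b):
        # projector decomposition: |0><0|_a I + |1><1|_a X_b
        P0 = np.array([[1, 0], [0, 0]], dtype=complex)
        P1 = np.array([[0, 0], [0, 1]], dtype=complex)
        X = np.array([[0, 1], [1, 0]], dtype=complex)
        opsA = [I2] * N
        opsA[a] = P0
        opsB = [I2] * N
        opsB[a] = P1
        opsB[b] = X
        outA, outB = opsA[0], opsB[0]
        for oa, ob in zip(opsA[1:], opsB[1:]):
            outA = np.kron(outA, oa)
            outB = np.kron(outB, ob)
        return outA + outB

    params = {"gamma": list(gammas), "beta": list(betas)}
    psi = np.zeros(2**N, dtype=complex)
    psi[0] = 1.0
    gates = list(circuit.prologue)
    for cost, mixer in circuit.blocks:
        gates.extend(cost)
        gates.extend(mixer)
    for gate in gates:
        angle = None
        if gate.slot is not None:
            kind, step = gate.slot
            angle = gate.scale * params[kind][step]
        if gate.name == "H":
            U = one_qubit(H, gate.qubits[0])
        elif gate.name == "RZ":
            RZ = np.diag([np.exp(-0.5j * angle), np.exp(0.5j * angle)])
            U = one_qubit(RZ, gate.qubits[0])
        elif gate.name == "RX":
            c, s = np.cos(angle / 2), np.sin(angle / 2)
            RX = np.array([[c, -1j * s], [-1j * s, c]])
            U = one_qubit(RX, gate.qubits[0])
        elif gate.name == "CNOT":
            U = cnot(*gate.qubits)
        psi = U @ psi
    return psi


def naive_diagonal(ham: PauliHamiltonian) -> np.ndarray:
    """Per-state, per-term summation oracle."""
    N = ham.n_qubits
    out = np.zeros(1 << N)
    for state in range(1 << N):
        bits = [(state >> (N - 1 - q)) & 1 for q in range(N)]
        for coeff, word in ham.terms:
            val = coeff
            for q, ch in enumerate(word):
                if ch == "Z":
                    val *= 1 - 2 * bits[q]
            out[state] += val
    return out


def random_circuit(rng, N, n_gates=12) -> ParamCircuit:
    cost = []
    kinds = ["H", "RZ", "RX"] + (["CNOT"] if N >= 2 else [])
    for _ in range(n_gates):
        kind = str(rng.choice(kinds))
        if kind == "CNOT":
            a, b = rng.choice(N, size=2, replace=False)
            cost.append(Gate("CNOT", (int(a), int(b))))
        elif kind == "H":
            cost.append(Gate("H", (int(rng.integers(N)),)))
        else:
            cost.append(
                Gate(kind, (int(rng.integers(N)),),
                     float(rng.uniform(-2, 2)), ("gamma", 0))
            )
    mixer = tuple(Gate("RX", (q,), 2.0, ("beta", 0)) for q in range(N))
    return ParamCircuit(n_qubits=N, prologue=(), blocks=((tuple(cost), mixer),))


# ---------------------------------------------------------------------------


class TestPauliHamiltonian:
    def test_duplicate_words_merged(self):
        ham = PauliHamiltonian.from_terms(2, [(1.0, "ZI"), (2.0, "ZI")])
        assert ham.terms == ((3.0, "ZI"),)

    def test_zero_terms_dropped(self):
        ham = PauliHamiltonian.from_terms(2, [(1.0, "ZI"), (-1.0, "ZI")])
        assert ham.terms == ()

    def test_bad_word_rejected(self):
        with pytest.raises(ValueError):
            PauliHamiltonian.from_terms(2, [(1.0, "ZQ")])
        with pytest.raises(ValueError):
            PauliHamiltonian.from_terms(2, [(1.0, "Z")])

    def test_text_format(self):
        ham = PauliHamiltonian.from_terms(3, [(0.5, "IZZ")])
        assert ham.to_text() == "0.5 IZZ\n"


class TestBuildCostHamiltonian:
    def test_demo_zz_word_census(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        zz = [w for _, w in ham.terms if w.count("Z") == 2]
        # 24 co-location + 24 repetition + 48 path pairs
        assert len(zz) == 96

    def test_demo_single_z_census(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        singles = [w for _, w in ham.terms if w.count("Z") == 1]
        assert len(singles) == 16  # one merged term per qubit

    def test_sparse_versus_all_pauli_bound(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        assert len(ham.terms) < 500
        assert 4 ** ham.n_qubits == 4294967296  # full Pauli-word space, n=4

    def test_demo_diagonal_argmin_is_type_a(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        energies = diagonal_energies(ham)
        argmin = np.flatnonzero(energies <= energies.min() + 1e-6)
        bitstrings = {format(int(i), "016b") for i in argmin}
        expected = {"".join(map(str, x)) for x in TYPE_A_ASSIGNMENTS}
        assert bitstrings == expected

    @pytest.mark.parametrize("n", [2, 3])
    def test_ranks_tours_like_tour_cost(self, n):
        from itertools import permutations

        from quboasm import Tour, tour_cost
        from quboasm.pipeline import encode_tour

        rng = np.random.default_rng(60 + n)
        tsp = random_tsp(rng, n)
        ham = build_cost_hamiltonian(tsp, w=1000.0)
        energies = diagonal_energies(ham)
        N = n * n
        pairs = []
        for order in permutations(range(n)):
            tour = Tour(order)
            x = encode_tour(tour)
            idx = int("".join(map(str, x)), 2)
            pairs.append((energies[idx], tour_cost(tsp, tour)))
        ranks_e = np.argsort([p[0] for p in pairs], kind="stable")
        ranks_c = np.argsort([p[1] for p in pairs], kind="stable")
        assert list(ranks_e) == list(ranks_c)

    def test_ground_state_agreement_random_n3(self):
        from quboasm import solve_exact, tsp_to_qubo

        for seed in range(20):
            rng = np.random.default_rng(seed)
            tsp = random_tsp(rng, 3)
            ham = build_cost_hamiltonian(tsp, w=1000.0)
            energies = diagonal_energies(ham)
            argmin = {
                format(int(i), "09b")
                for i in np.flatnonzero(energies <= energies.min() + 1e-6)
            }
            qubo = tsp_to_qubo(tsp, a=0.0, b=100.0, c=100.0)
            qubo_argmin = {
                "".join(map(str, r.configuration))
                for r in solve_exact(qubo).minima()
            }
            assert argmin == qubo_argmin


class TestDiagonalEnergies:
    def test_constant_term(self):
        ham = PauliHamiltonian.from_terms(3, [(2.5, "III")])
        np.testing.assert_allclose(diagonal_energies(ham), 2.5)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(8)
        words = ["ZIIIII", "IZZIII", "IIIZIZ", "ZZZZZZ", "IIIIII"]
        ham = PauliHamiltonian.from_terms(
            6, [(float(rng.uniform(-3, 3)), w) for w in words]
        )
        np.testing.assert_allclose(
            diagonal_energies(ham), naive_diagonal(ham), atol=1e-12
        )

    def test_non_diagonal_rejected(self):
        ham = PauliHamiltonian.from_terms(2, [(1.0, "XI")])
        with pytest.raises(ValueError):
            diagonal_energies(ham)


class TestBuildAnsatz:
    def test_minimal_structure(self):
        ham = PauliHamiltonian.from_terms(1, [(1.0, "Z")])
        circ = build_ansatz(ham, steps=1)
        names = [g.name for g in circ.prologue] + [
            g.name for cost, mixer in circ.blocks for g in cost + mixer
        ]
        assert names == ["H", "RZ", "RX"]

    def test_demo_one_block_16_mixer_gates(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        circ = build_ansatz(ham, steps=1)
        assert circ.steps == 1
        cost, mixer = circ.blocks[0]
        assert len(mixer) == 16
        assert all(g.name == "RX" for g in mixer)
        # each ZZ term compiles to a CNOT-RZ-CNOT sandwich
        assert sum(1 for g in cost if g.name == "CNOT") == 2 * 96

    def test_two_steps_parameter_slots(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        circ = build_ansatz(ham, steps=2)
        assert circ.steps == 2
        for step, (cost, mixer) in enumerate(circ.blocks):
            for g in cost:
                if g.slot is not None:
                    assert g.slot == ("gamma", step)
            for g in mixer:
                assert g.slot == ("beta", step)

    def test_rz_scale_is_twice_coefficient(self):
        ham = PauliHamiltonian.from_terms(2, [(3.0, "ZI"), (-1.5, "ZZ")])
        circ = build_ansatz(ham, steps=1)
        cost, _ = circ.blocks[0]
        scales = {g.scale for g in cost if g.name == "RZ"}
        assert scales == {6.0, -3.0}


class TestSimulateStatevector:
    def test_empty_circuit(self):
        circ = ParamCircuit(n_qubits=3, prologue=(), blocks=())
        state = simulate_statevector(circ, [], [])
        expected = np.zeros(8)
        expected[0] = 1.0
        np.testing.assert_allclose(state, expected)

    def test_prologue_equal_superposition(self):
        ham = PauliHamiltonian.from_terms(4, [(1.0, "ZIII")])
        circ = build_ansatz(ham, steps=1)
        circ = ParamCircuit(n_qubits=4, prologue=circ.prologue, blocks=())
        state = simulate_statevector(circ, [], [])
        np.testing.assert_allclose(state, np.full(16, 0.25), atol=1e-12)

    @pytest.mark.parametrize("N", [1, 2, 3, 4])
    def test_matches_kronecker_oracle(self, N):
        for trial in range(25):
            rng = np.random.default_rng(1000 * N + trial)
            circ = random_circuit(rng, N)
            gammas = [float(rng.uniform(0, 2 * np.pi))]
            betas = [float(rng.uniform(0, 2 * np.pi))]
            fast = simulate_statevector(circ, gammas, betas)
            slow = kron_oracle(circ, gammas, betas)
            np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_unitarity_demo_ansatz(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        circ = build_ansatz(ham, steps=1)
        rng = np.random.default_rng(4)
        for _ in range(3):
            state = simulate_statevector(
                circ, [rng.uniform(0, 2 * np.pi)], [rng.uniform(0, 2 * np.pi)]
            )
            assert abs(np.linalg.norm(state) - 1.0) < 1e-9

    def test_parameter_count_checked(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        circ = build_ansatz(ham, steps=1)
        with pytest.raises(ValueError):
            simulate_statevector(circ, [0.1, 0.2], [0.3])


class TestExpectation:
    def test_basis_state(self):
        ham = PauliHamiltonian.from_terms(2, [(1.0, "ZI"), (0.5, "ZZ")])
        state = np.zeros(4, dtype=complex)
        state[2] = 1.0  # |10>: z = (-1, +1)
        assert expectation(state, ham) == pytest.approx(-1.0 - 0.5)

    def test_equal_superposition_is_mean(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        state = np.full(1 << 16, 2.0 ** -8, dtype=complex)
        assert expectation(state, ham) == pytest.approx(
            diagonal_energies(ham).mean(), rel=1e-9
        )

    def test_zero_angle_limit(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        circ = build_ansatz(ham, steps=1)
        state = simulate_statevector(circ, [0.0], [0.0])
        assert expectation(state, ham) == pytest.approx(
            diagonal_energies(ham).mean(), abs=1e-6
        )

    def test_unnormalized_rejected(self):
        ham = PauliHamiltonian.from_terms(1, [(1.0, "Z")])
        with pytest.raises(ValueError):
            expectation(np.array([1.0, 1.0]), ham)


class TestSampleCounts:
    def test_basis_state_all_counts(self):
        state = np.zeros(4, dtype=complex)
        state[3] = 1.0
        counts = sample_counts(state, shots=100, seed=0)
        assert counts == {"11": 100}

    def test_equal_superposition_binomial_bound(self):
        state = np.full(4, 0.5, dtype=complex)
        counts = sample_counts(state, shots=10000, seed=123)
        sigma = np.sqrt(10000 * 0.25 * 0.75)
        for key in ("00", "01", "10", "11"):
            assert abs(counts[key] - 2500) < 5 * sigma

    def test_shots_zero_bypass(self):
        state = np.array([np.sqrt(0.25), 0, 0, np.sqrt(0.75)], dtype=complex)
        probs = sample_counts(state, shots=0)
        assert probs == pytest.approx({"00": 0.25, "11": 0.75})

    def test_deterministic_given_seed(self):
        state = np.full(8, np.sqrt(1 / 8), dtype=complex)
        assert sample_counts(state, 50, seed=7) == sample_counts(state, 50, seed=7)


class TestVariationalLoop:
    def test_single_qubit_reaches_near_optimum(self):
        # cost -Z has ground energy -1; a depth-1 ansatz can reach it
        ham = PauliHamiltonian.from_terms(1, [(-1.0, "Z")])
        result = optimize_angles(
            ham, steps=1, max_iter=100, restarts=10, seed=0
        )
        assert result.best_expectation <= -0.99

    def test_trace_non_increasing(self, demo_tsp):
        result = run_qaoa(demo_tsp, restarts=3, max_iter=10, seed=5)
        trace = np.array(result.trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_improves_on_zero_angles(self, demo_tsp):
        ham = build_cost_hamiltonian(demo_tsp)
        zero_angle = diagonal_energies(ham).mean()
        result = run_qaoa(demo_tsp, restarts=3, max_iter=15, seed=17)
        assert result.best_expectation <= zero_angle

    def test_zero_angles_uniform_probabilities(self, demo_tsp):
        # identity evolution of the equal superposition
        ham = build_cost_hamiltonian(demo_tsp)
        circ = build_ansatz(ham, steps=1)
        state = simulate_statevector(circ, [0.0], [0.0])
        np.testing.assert_allclose(
            np.abs(state) ** 2, np.full(65536, 1.0 / 65536), atol=1e-12
        )

    def test_unknown_optimizer_listed(self, demo_tsp):
        with pytest.raises(ValueError, match="Nelder-Mead"):
            run_qaoa(demo_tsp, optimizer="ADAM")

    def test_reproducible_given_seed(self, demo_tsp):
        a = run_qaoa(demo_tsp, restarts=2, max_iter=5, seed=3)
        b = run_qaoa(demo_tsp, restarts=2, max_iter=5, seed=3)
        assert a.gammas == b.gammas and a.betas == b.betas
        assert a.trace == b.trace

    def test_decoded_states_attached(self, demo_tsp):
        result = run_qaoa(demo_tsp, restarts=1, max_iter=5, seed=1, top_k=3)
        assert len(result.decoded) == 3
        for entry in result.decoded:
            assert set(entry) >= {"bitstring", "probability", "valid"}
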