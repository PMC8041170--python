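# quboasm

Reference-free de novo DNA assembly by the overlap-layout-consensus route,
encoded as a directed traveling-salesman problem, reduced to a QUBO/Ising
model, and solved three ways:

* **exhaustive enumeration** — the exact solver (guard: ≤ 24 variables);
* **simulated annealing** — a seeded classical stand-in for a quantum
  annealer, sampling the Ising transform;
* **QAOA** — a cost Hamiltonian built as a weighted sum of Pauli-Z
  products, compiled to an alternating RZ/CNOT + RX ansatz, simulated on
  a dense statevector and optimized with gradient-free SciPy optimizers.

Ground-state configurations are decoded into tours (one binary variable
per node/time-slot pair) and stitched into an assembled sequence by
trimming exact suffix-prefix overlaps.

## Library quick start

```python
import quboasm as q

reads = q.generate_circular_reads("ATGGCGTGCA", [0, 3, 6, 9], 10)
tsp   = q.reads_to_tsp(reads)              # weights = negated overlaps
qubo  = q.tsp_to_qubo(tsp, a=0, b=13, c=13)
best  = q.solve_exact(qubo).minima()       # 4 degenerate ground states
tour  = q.decode_assignment(best[0].configuration, tsp.n).tour
print(q.stitch(reads, tour).sequence)      # ATGGCGTGCAATGGCGTGC
```

## CLI

The `quboasm` command exposes each stage:

```sh
quboasm overlap     --genome ATGGCGTGCA --offsets 0,3,6,9 --read-length 10
quboasm encode      --reads ATGGCGTGCA,GCGTGCAATG,TGCAATGGCG,AATGGCGTGC
quboasm solve-exact --fasta reads.fasta
quboasm solve-sa    --fasta reads.fasta --samples 1000 --sweeps 1000 --seed 42
quboasm solve-qaoa  --fasta reads.fasta --steps 1 --restarts 40 --seed 7
quboasm assemble    --fasta reads.fasta --tour 0,1,2,3
quboasm pipeline    --genome ATGGCGTGCA --offsets 0,3,6,9 --read-length 10 \
                    --solver exact --out report.json
```

All reports are JSON; stochastic solvers are fully reproducible given
`--seed`.

## Layout

| module | contents |
| --- | --- |
| `quboasm.reads` | FASTA input, circular-window read generator, exact suffix-prefix overlaps, TSP construction |
| `quboasm.tsp` | tour enumeration/scoring oracle (start-fixed, direction kept) |
| `quboasm.qubo` | TSP → QUBO encoding, interaction census, exact QUBO ⇄ Ising transform |
| `quboasm.solvers` | exhaustive enumeration, seeded Metropolis simulated annealing |
| `quboasm.qaoa` | Pauli cost Hamiltonian, ansatz compiler, statevector simulator, variational loop |
| `quboasm.pipeline` | assignment decoding, stitching, end-to-end orchestration |
| `quboasm.cli` | click command-line interface |

Scope notes: overlaps are exact-match only (no error tolerance, no
reverse complements, no consensus polishing); hardware annealer execution
and topology embedding are out of scope.
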