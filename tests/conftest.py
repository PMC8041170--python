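import numpy as np
import pytest

from quboasm import generate_circular_reads, reads_to_tsp, tsp_to_qubo

# the worked four-read example: length-10 windows of a circular genome
DEMO_GENOME = "ATGGCGTGCA"
DEMO_OFFSETS = [0, 3, 6, 9]
DEMO_READ_LENGTH = 10

# published directed edge weights of the four-read instance
DEMO_WEIGHTS = {
    (0, 1): -7, (1, 2): -7, (2, 3): -7, (3, 0): -9,
    (1, 0): -3, (2, 1): -3, (3, 2): -3, (0, 3): -1,
    (0, 2): -4, (1, 3): -4, (2, 0): -6, (3, 1): -6,
}

# the four degenerate ground-state assignment vectors (rotations of the
# tour 0->1->2->3), in the n{i}t{p} variable order
TYPE_A_ASSIGNMENTS = [
    (1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1),
    (0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0),
    (0, 0, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 0),
    (0, 0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0),
]


@pytest.fixture(scope="session")
def demo_readset():
    return generate_circular_reads(DEMO_GENOME, DEMO_OFFSETS, DEMO_READ_LENGTH)


@pytest.fixture(scope="session")
def demo_tsp(demo_readset):
    return reads_to_tsp(demo_readset)


@pytest.fixture(scope="session")
def demo_qubo(demo_tsp):
    return tsp_to_qubo(demo_tsp, a=0.0, b=13.0, c=13.0)


def random_tsp(rng: np.random.Generator, n: int):
    """Random directed complete instance with integer weights."""
    from quboasm import TSPInstance

    w = rng.integers(-9, 0, size=(n, n)).astype(float)
    np.fill_diagonal(w, 0.0)
    return TSPInstance(n=n, weights=w, labels=tuple(f"node{i}" for i in range(n)))
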