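import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from flowscales import FlowGraph, RandomWalkModel


def enumerate_set_partitions(n):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    out = []

    def rec(i, labels, mx):
        if i == n:
            out.append(np.array(labels))
            return
        for lab in range(mx + 1):
            labels.append(lab)
            rec(i + 1, labels, max(mx, lab + 1))
            labels.pop()

    rec(0, [], 0)
    return out


def random_strongly_connected(rng, n=6, density=0.5, max_tries=200):
    """Random strongly connected FlowGraph with log-normal weights."""
    for _ in range(max_tries):
        A = (rng.random((n, n)) < density) * rng.lognormal(0.0, 1.0, (n, n))
        np.fill_diagonal(A, 0.0)
        ncomp, _ = connected_components(sparse.csr_matrix(A > 0), connection="strong")
        if ncomp == 1:
            return FlowGraph(nodes=[f"n{i}" for i in range(n)], A=A, intra=np.zeros(n))
    raise RuntimeError("failed to sample a strongly connected graph")


@pytest.fixture
def cycle3():
    """Directed 3-cycle with unit weights."""
    A = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    return FlowGraph(nodes=["a", "b", "c"], A=A, intra=np.zeros(3))


@pytest.fixture
def cycle3_model(cycle3):
    return RandomWalkModel.from_graph(cycle3)


@pytest.fixture
def small_random_graph():
    rng = np.random.default_rng(42)
    return random_strongly_connected(rng, n=8, density=0.6)
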