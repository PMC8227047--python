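import numpy as np
import pytest

from strucnet.construct import BinaryNetwork
from strucnet.io import WeightedConnectome


def network_from_edges(n, edges, labels=None):
    labels = labels or [f"v{i}" for i in range(n)]
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adj, labels)


def random_network(rng, n_min=4, n_max=12, p=None):
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.2, 0.8)) if p is None else p
    draw = rng.random((n, n))
    adj = np.triu(draw < p, k=1)
    adj = (adj | adj.T).astype(int)
    return BinaryNetwork(adj, [f"v{i}" for i in range(n)])


@pytest.fixture
def triangle():
    return network_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path4():
    return network_from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def star5():
    return network_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def k4_minus_edge():
    return network_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])


@pytest.fixture
def two_disjoint_edges():
    return network_from_edges(4, [(0, 1), (2, 3)])


@pytest.fixture
def k5():
    return network_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])


def tiny_connectome(weights, labels=("A", "B", "C")):
    """Connectome from a dict {(i, j): w} over the given labels."""
    n = len(labels)
    m = np.zeros((n, n))
    for (i, j), w in weights.items():
        m[i, j] = m[j, i] = w
    return WeightedConnectome(m, list(labels))
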