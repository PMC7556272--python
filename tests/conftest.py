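import numpy as np
import pytest

from mcinet.connectivity import FCMatrix, ThresholdedNetwork


def net_from_adjacency(adj: np.ndarray) -> ThresholdedNetwork:
    adj = np.asarray(adj, dtype=float)
    k = int((np.triu(adj, 1) > 0).sum())
    n = adj.shape[0]
    return ThresholdedNetwork(adjacency=adj, sparsity=k / (n * (n - 1) / 2), retained_edges=k)


def random_weighted_net(
    rng: np.random.Generator, n: int, density: float = 0.5
) -> ThresholdedNetwork:
    """Random connected-ish weighted graph with weights in (0, 1]."""
    adj = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    keep = rng.random(iu.size) < density
    w = rng.uniform(0.05, 1.0, iu.size)
    adj[iu[keep], ju[keep]] = w[keep]
    adj += adj.T
    # ensure at least one edge
    if not adj.any():
        adj[0, 1] = adj[1, 0] = 0.5
    return net_from_adjacency(adj)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def triangle() -> ThresholdedNetwork:
    adj = np.zeros((3, 3))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        adj[i, j] = adj[j, i] = 1.0
    return net_from_adjacency(adj)


@pytest.fixture
def path3() -> ThresholdedNetwork:
    """Unit-weight 3-node path 0-1-2."""
    adj = np.zeros((3, 3))
    adj[0, 1] = adj[1, 0] = 1.0
    adj[1, 2] = adj[2, 1] = 1.0
    return net_from_adjacency(adj)


@pytest.fixture
def star5() -> ThresholdedNetwork:
    """Unit-weight star, node 0 is the center of 4 leaves."""
    adj = np.zeros((5, 5))
    for leaf in range(1, 5):
        adj[0, leaf] = adj[leaf, 0] = 1.0
    return net_from_adjacency(adj)


@pytest.fixture
def random_fc(rng) -> FCMatrix:
    n = 20
    vals = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    vals[iu, ju] = rng.uniform(0.01, 0.99, iu.size)
    vals += vals.T
    return FCMatrix(values=vals, roi_names=[f"R{i}" for i in range(n)])
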