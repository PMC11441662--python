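import numpy as np
import pytest

from overlapnet.netio import CorrelationMatrix, WeightedNetwork, threshold_by_density


@pytest.fixture
def path_graph_net() -> WeightedNetwork:
    """Unit-weight path 0-1-2."""
    adj = np.zeros((3, 3))
    adj[0, 1] = adj[1, 0] = 1.0
    adj[1, 2] = adj[2, 1] = 1.0
    return WeightedNetwork(adjacency=adj, density=2 / 3, node_ids=["0", "1", "2"])


@pytest.fixture
def triangle_net() -> WeightedNetwork:
    """Unit-weight triangle on 3 nodes."""
    adj = np.ones((3, 3)) - np.eye(3)
    return WeightedNetwork(adjacency=adj, density=1.0, node_ids=["0", "1", "2"])


@pytest.fixture
def two_triangles_net() -> WeightedNetwork:
    """Two vertex-disjoint unit-weight triangles (6 nodes, 6 edges)."""
    adj = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        adj[a, b] = adj[b, a] = 1.0
    return WeightedNetwork(adjacency=adj, density=6 / 15, node_ids=[str(i) for i in range(6)])


def random_network(n_nodes: int, density: float, seed: int) -> WeightedNetwork:
    """Random positive-correlation network for oracle comparisons."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.01, 0.99, size=(n_nodes, n_nodes))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return threshold_by_density(CorrelationMatrix(values=m, node_ids=[str(i) for i in range(n_nodes)]), density)
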