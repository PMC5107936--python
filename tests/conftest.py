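import networkx as nx
import numpy as np
import pytest

from covnet import BinaryNetwork, CovarianceSpec, generate_cohort


def net_from_adjacency(adj, regions=None) -> BinaryNetwork:
    """Wrap a plain 0/1 adjacency matrix as a BinaryNetwork."""
    adj = np.asarray(adj, dtype=np.uint8)
    n = adj.shape[0]
    if regions is None:
        regions = [f"n{i}" for i in range(n)]
    k = int(adj.sum())
    return BinaryNetwork(
        regions=regions,
        adjacency=adj,
        density=k / (n * (n - 1)) if n > 1 else 0.0,
        k_nonzero=k,
    )


def net_from_nx(g: nx.Graph) -> BinaryNetwork:
    return net_from_adjacency(nx.to_numpy_array(g, nodelist=sorted(g.nodes)))


def random_connected_net(rng, max_nodes=7) -> BinaryNetwork:
    """A random connected simple graph with 2..max_nodes nodes."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.3, 0.9))
        a = np.triu((rng.random((n, n)) < p), 1).astype(np.uint8)
        a |= a.T
        g = nx.from_numpy_array(a)
        if a.sum() > 0 and nx.is_connected(g):
            return net_from_adjacency(a)


@pytest.fixture
def star5() -> BinaryNetwork:
    return net_from_nx(nx.star_graph(4))


@pytest.fixture
def complete4() -> BinaryNetwork:
    return net_from_nx(nx.complete_graph(4))


@pytest.fixture
def path4() -> BinaryNetwork:
    return net_from_nx(nx.path_graph(4))


@pytest.fixture
def cycle6() -> BinaryNetwork:
    return net_from_nx(nx.cycle_graph(6))


@pytest.fixture
def two_triangles() -> BinaryNetwork:
    g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return net_from_nx(g)


@pytest.fixture(scope="session")
def modular_cohort():
    """Two identical 20-region, 4-module groups (null-effect cohort)."""
    spec = CovarianceSpec(
        partition=tuple(i // 5 for i in range(20)),
        r_within=0.5,
        r_between=0.1,
    )
    return generate_cohort(spec, spec, 43, 73, seed=11)
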