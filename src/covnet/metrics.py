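"""Node- and network-level graph statistics on binary networks.

All measures operate on an undirected, unweighted :class:`BinaryNetwork`.
Conventions for disconnected networks (which occur at the sparse end of the
density grid):

* the characteristic path length Lp averages over mutually reachable pairs
  only, keeping Lp finite;
* efficiency uses 1/inf = 0 for unreachable pairs, so it needs no special
  case;
* nodes of degree < 2 contribute 0 (they are not excluded) to the means of
  the clustering coefficient and local efficiency, keeping denominators
  fixed across groups.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .construction import BinaryNetwork

__all__ = [
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "modularity",
    "modularity_q",
    "node_betweenness",
    "identify_hubs",
    "largest_component_relative_size",
    "to_networkx",
]


def to_networkx(net: BinaryNetwork) -> nx.Graph:
    """networkx view of the adjacency; all regions present as nodes 0..N-1."""
    g = nx.from_numpy_array(net.adjacency)
    g.add_nodes_from(range(net.n_regions))
    return g


def _hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths; inf for unreachable.

    Small matrices use a vectorised boolean-matmul BFS (one matmul per hop,
    much faster than sparse Dijkstra at connectome scale); larger ones fall
    back to scipy's csgraph.
    """
    n = adj.shape[0]
    if adj.sum() == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    if n > 256:
        return shortest_path(csr_matrix(adj), method="D", unweighted=True)
    a = adj.astype(bool)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a] = 1.0
    known = a | np.eye(n, dtype=bool)
    frontier = a
    hop = 1
    while True:
        nxt = (frontier @ a) & ~known
        if not nxt.any():
            return d
        hop += 1
        d[nxt] = hop
        known |= nxt
        frontier = nxt


def clustering_coefficient(net: BinaryNetwork) -> float:
    """Mean over nodes of 2 t_i / (k_i (k_i - 1)); degree-<2 nodes count 0."""
    a = net.adjacency.astype(np.int64)
    n = a.shape[0]
    if n == 0:
        return 0.0
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def characteristic_path_length(
    net: BinaryNetwork, _distances: np.ndarray | None = None
) -> float:
    """Mean shortest-path length over mutually reachable distinct node pairs."""
    if net.k_nonzero == 0:
        raise ValueError("characteristic path length undefined: no edges")
    d = _hop_distances(net.adjacency) if _distances is None else _distances
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = off & np.isfinite(d)
    return float(d[finite].mean())


def global_efficiency(
    net: BinaryNetwork, _distances: np.ndarray | None = None
) -> float:
    """Mean of 1/d_ij over ordered pairs of distinct nodes (1/inf = 0)."""
    n = net.n_regions
    if n < 2:
        return 0.0
    d = _hop_distances(net.adjacency) if _distances is None else _distances
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    return float(np.where(np.isfinite(inv), inv, 0.0).mean())


def _subgraph_efficiency(sub: np.ndarray) -> float:
    m = sub.shape[0]
    if m < 2:
        return 0.0
    d = _hop_distances(sub)
    off = ~np.eye(m, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    return float(np.where(np.isfinite(inv), inv, 0.0).mean())


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean over nodes of the global efficiency of the subgraph induced on
    each node's neighbours; nodes with < 2 neighbours contribute 0."""
    a = net.adjacency
    n = a.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nb = np.nonzero(a[i])[0]
        if nb.size >= 2:
            total += _subgraph_efficiency(a[np.ix_(nb, nb)])
    return total / n


def modularity_q(net: BinaryNetwork, labels) -> float:
    """Newman-Girvan modularity Q = sum_c (e_c/m - (d_c/2m)^2) of a given
    partition, with e_c within-community edges and d_c the community degree
    sum."""
    labels = np.asarray(labels)
    a = net.adjacency.astype(np.int64)
    m = a.sum() / 2.0
    if m == 0:
        raise ValueError("modularity undefined: no edges")
    deg = a.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e_c = a[np.ix_(idx, idx)].sum() / 2.0
        d_c = deg[idx].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def modularity(
    net: BinaryNetwork, seed: int = 0, n_restarts: int = 20
) -> tuple[float, np.ndarray]:
    """Best-of-restarts Louvain partition and its Newman-Girvan Q.

    The heuristic is stochastic; ``n_restarts`` independent seeded runs are
    performed and the partition with the highest Q is returned, with Q
    recomputed from the standard formula.
    """
    if net.k_nonzero == 0:
        raise ValueError("modularity undefined: no edges")
    g = to_networkx(net)
    ss = np.random.SeedSequence(seed)
    best_q, best_labels = -np.inf, None
    for child in ss.spawn(max(1, n_restarts)):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        communities = nx.community.louvain_communities(g, seed=run_seed)
        labels = np.empty(net.n_regions, dtype=np.int64)
        for c, members in enumerate(communities):
            labels[list(members)] = c
        q = modularity_q(net, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def node_betweenness(net: BinaryNetwork) -> np.ndarray:
    """Unnormalised shortest-path betweenness per region.

    Fractional contributions of all shortest paths are counted (Brandes);
    endpoints are excluded; each unordered pair contributes once.
    """
    bc = nx.betweenness_centrality(to_networkx(net), normalized=False)
    return np.array([bc[i] for i in range(net.n_regions)], dtype=float)


def identify_hubs(net: BinaryNetwork) -> pd.DataFrame:
    """Hub table: betweenness normalised by the network mean; hubs exceed 2.

    Returns a DataFrame with columns ``region``, ``betweenness``,
    ``normalized_betweenness`` and ``is_hub``, sorted by normalised
    betweenness descending.  A node is a hub iff its betweenness is more
    than twice the network average.
    """
    if net.k_nonzero == 0:
        raise ValueError("hub detection undefined: no edges")
    bc = node_betweenness(net)
    mean = bc.mean()
    if mean == 0:
        warnings.warn("all betweenness values are 0; no hubs", stacklevel=2)
        nb = np.zeros_like(bc)
    else:
        nb = bc / mean
    table = pd.DataFrame(
        {
            "region": net.regions,
            "betweenness": bc,
            "normalized_betweenness": nb,
            "is_hub": nb > 2.0,
        }
    )
    return table.sort_values(
        "normalized_betweenness", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def largest_component_relative_size(net: BinaryNetwork) -> float:
    """Size of the largest connected component over the total region count.

    Isolated nodes count as components of size 1.
    """
    n = net.n_regions
    if n == 0:
        return 0.0
    _, labels = connected_components(csr_matrix(net.adjacency), directed=False)
    return float(np.bincount(labels).max() / n)
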