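"""Independent brute-force graph-metric oracle for tiny graphs.

Everything here works by exhaustive enumeration (all simple paths, all node
triples) using plain Python, deliberately sharing no code path with the
package implementation.  Feasible for graphs of up to ~8 nodes.
"""

from itertools import combinations

import numpy as np


def _all_simple_paths(adj, s, t):
    """Every simple path from s to t, by DFS."""
    n = adj.shape[0]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for v in range(n):
            if adj[last, v] and v not in path:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def shortest_path_info(adj, s, t):
    """(distance, number of shortest paths, list of shortest paths).

    distance is inf when t is unreachable from s.
    """
    paths = _all_simple_paths(adj, s, t)
    if not paths:
        return np.inf, 0, []
    d = min(len(p) - 1 for p in paths)
    shortest = [p for p in paths if len(p) - 1 == d]
    return d, len(shortest), shortest


def clustering(adj):
    """Mean clustering coefficient; triangles counted by triple enumeration."""
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            continue
        links = sum(1 for a, b in combinations(nb, 2) if adj[a, b])
        total += links / (len(nb) * (len(nb) - 1) / 2)
    return total / n if n else 0.0


def path_length(adj):
    """Mean distance over mutually reachable unordered pairs."""
    n = adj.shape[0]
    dists = [
        shortest_path_info(adj, s, t)[0]
        for s, t in combinations(range(n), 2)
    ]
    finite = [d for d in dists if np.isfinite(d)]
    if not finite:
        raise ValueError("no reachable pairs")
    return sum(finite) / len(finite)


def global_eff(adj):
    """Mean of 1/d over ordered distinct pairs; unreachable contributes 0."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for s, t in combinations(range(n), 2):
        d, _, _ = shortest_path_info(adj, s, t)
        if np.isfinite(d):
            total += 2.0 / d
    return total / (n * (n - 1))


def local_eff(adj):
    """Mean over nodes of global_eff of the neighbour-induced subgraph."""
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) >= 2:
            total += global_eff(adj[np.ix_(nb, nb)])
    return total / n if n else 0.0


def betweenness(adj):
    """Endpoint-excluded shortest-path betweenness, each unordered pair once,
    with fractional credit over the shortest paths of the pair."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        d, sigma, shortest = shortest_path_info(adj, s, t)
        if not np.isfinite(d) or sigma == 0:
            continue
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / sigma
    return bc
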