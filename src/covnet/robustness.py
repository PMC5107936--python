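"""Network resilience to random failures and targeted attacks.

At a fixed connection density (0.19 by default in the pipeline), nodes or
edges are removed either uniformly at random (failures, averaged over many
repetitions) or cumulatively in decreasing order of their betweenness
centrality (targeted attacks).  The outcome at each removal fraction is the
relative size of the largest connected component: the order of the biggest
mutually reachable subnetwork divided by the *total* number of regions.

For targeted attacks the betweenness ranking is computed once on the intact
network by default (static ordering); adaptive recomputation after each
removal is available via ``recompute=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .construction import BinaryNetwork
from .metrics import node_betweenness, to_networkx

__all__ = ["RobustnessCurve", "random_failure_curve", "targeted_attack_curve"]

MODES = ("random_node", "random_edge", "targeted_node", "targeted_edge")


def default_fractions(step: float = 0.05) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


@dataclass
class RobustnessCurve:
    mode: str
    fractions_removed: np.ndarray
    relative_size: np.ndarray
    n_reps: int
    sd: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        # mean of per-repetition monotone curves is monotone; guard anyway
        diffs = np.diff(self.relative_size)
        assert np.all(diffs <= 1e-9), "robustness curve must be non-increasing"

    def to_tsv(self, path) -> None:
        cols = {
            "fraction_removed": self.fractions_removed,
            "relative_largest_component": self.relative_size,
        }
        if self.sd is not None:
            cols["sd"] = self.sd
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _largest_after_node_removal(adj: np.ndarray, removed: np.ndarray, n_total: int) -> float:
    keep = np.setdiff1d(np.arange(adj.shape[0]), removed, assume_unique=False)
    if keep.size == 0:
        return 0.0
    sub = adj[np.ix_(keep, keep)]
    _, labels = connected_components(csr_matrix(sub), directed=False)
    return float(np.bincount(labels).max() / n_total)


def _largest_after_edge_removal(
    n: int, edges: np.ndarray, keep_mask: np.ndarray, n_total: int
) -> float:
    adj = np.zeros((n, n), dtype=np.uint8)
    kept = edges[keep_mask]
    adj[kept[:, 0], kept[:, 1]] = 1
    adj |= adj.T
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return float(np.bincount(labels).max() / n_total)


def random_failure_curve(
    net: BinaryNetwork,
    mode: str = "node",
    n_reps: int = 1000,
    seed: int = 0,
    fractions: np.ndarray | None = None,
) -> RobustnessCurve:
    """Mean largest-component curve under uniform random removal.

    For each repetition a single random removal order is drawn; at every
    grid fraction the corresponding prefix (rounded to the nearest count)
    is removed and the relative largest-component size recorded.  The curve
    is the mean over ``n_reps`` repetitions.
    """
    if mode not in ("node", "edge"):
        raise ValueError("mode must be 'node' or 'edge'")
    if net.k_nonzero == 0:
        raise ValueError("robustness undefined: no edges")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fractions = default_fractions() if fractions is None else np.asarray(fractions)
    rng = np.random.default_rng(seed)
    n = net.n_regions
    edges = net.edges()
    n_items = n if mode == "node" else len(edges)
    counts = np.rint(fractions * n_items).astype(int)

    sizes = np.empty((n_reps, len(fractions)))
    for rep in range(n_reps):
        order = rng.permutation(n_items)
        for k, c in enumerate(counts):
            if mode == "node":
                sizes[rep, k] = _largest_after_node_removal(
                    net.adjacency, order[:c], n
                )
            else:
                keep = np.ones(n_items, dtype=bool)
                keep[order[:c]] = False
                sizes[rep, k] = _largest_after_edge_removal(n, edges, keep, n)
    return RobustnessCurve(
        mode=f"random_{mode}",
        fractions_removed=fractions,
        relative_size=sizes.mean(axis=0),
        sd=sizes.std(axis=0),
        n_reps=n_reps,
    )


def _static_node_order(net: BinaryNetwork) -> np.ndarray:
    bc = node_betweenness(net)
    # descending betweenness, ties by smaller region index
    return np.lexsort((np.arange(len(bc)), -bc))


def _static_edge_order(net: BinaryNetwork) -> list[tuple[int, int]]:
    ebc = nx.edge_betweenness_centrality(to_networkx(net), normalized=False)
    items = sorted(
        ((tuple(sorted(e)), v) for e, v in ebc.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return [e for e, _ in items]


def targeted_attack_curve(
    net: BinaryNetwork,
    mode: str = "node",
    fractions: np.ndarray | None = None,
    recompute: bool = False,
) -> RobustnessCurve:
    """Largest-component curve under betweenness-ordered removal.

    Nodes (or edges) are removed cumulatively in decreasing order of their
    betweenness centrality on the intact network; with ``recompute=True``
    the ranking is recomputed among the survivors after every removal.
    Ties break by smaller region index (nodes) or lexicographic endpoint
    pair (edges).
    """
    if mode not in ("node", "edge"):
        raise ValueError("mode must be 'node' or 'edge'")
    if net.k_nonzero == 0:
        raise ValueError("robustness undefined: no edges")
    fractions = default_fractions() if fractions is None else np.asarray(fractions)
    n = net.n_regions
    edges = net.edges()
    n_items = n if mode == "node" else len(edges)
    counts = np.rint(fractions * n_items).astype(int)

    if recompute:
        order = _adaptive_order(net, mode, n_items)
    elif mode == "node":
        order = list(_static_node_order(net))
    else:
        order = _static_edge_order(net)

    sizes = np.empty(len(fractions))
    for k, c in enumerate(counts):
        if mode == "node":
            sizes[k] = _largest_after_node_removal(
                net.adjacency, np.asarray(order[:c], dtype=int), n
            )
        else:
            removed = set(order[:c])
            keep = np.array(
                [tuple(e) not in removed for e in edges], dtype=bool
            )
            sizes[k] = _largest_after_edge_removal(n, edges, keep, n)
    return RobustnessCurve(
        mode=f"targeted_{mode}",
        fractions_removed=fractions,
        relative_size=sizes,
        n_reps=1,
    )


def _adaptive_order(net: BinaryNetwork, mode: str, n_items: int):
    """Removal order with betweenness recomputed among survivors."""
    g = to_networkx(net)
    order = []
    for _ in range(n_items):
        if mode == "node":
            bc = nx.betweenness_centrality(g, normalized=False)
            pick = min(bc, key=lambda v: (-bc[v], v))
            g.remove_node(pick)
        else:
            if g.number_of_edges() == 0:
                break
            ebc = nx.edge_betweenness_centrality(g, normalized=False)
            pick = min(
                (tuple(sorted(e)) for e in ebc),
                key=lambda e: (-ebc.get(e, ebc.get((e[1], e[0]), 0.0)), e),
            )
            g.remove_edge(*pick)
        order.append(pick)
    return order
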