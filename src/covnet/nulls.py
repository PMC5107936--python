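"""Degree-matched random reference networks and small-world coefficients.

The small-world coefficients normalise the empirical clustering coefficient
Cp and characteristic path length Lp by their means over an ensemble of
random networks with the *same degree sequence*:

    gamma = Cp / <Cp_rand>,   lambda = Lp / <Lp_rand>,   sigma = gamma / lambda

sigma > 1 indicates small-world organisation (more clustered than random at
comparable path length).  Nulls are produced by Maslov-Sneppen double edge
swaps, which preserve every node's degree exactly and never introduce
self-loops or multi-edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .construction import BinaryNetwork
from .metrics import characteristic_path_length, clustering_coefficient

__all__ = [
    "NullEnsemble",
    "SmallWorldParams",
    "rewire_degree_preserving",
    "build_null_ensemble",
    "small_world_params",
]


@dataclass
class NullEnsemble:
    n_nulls: int
    cp_values: np.ndarray
    lp_values: np.ndarray

    @property
    def cp_rand(self) -> float:
        return float(self.cp_values.mean())

    @property
    def lp_rand(self) -> float:
        return float(self.lp_values.mean())


@dataclass
class SmallWorldParams:
    gamma: float
    lam: float
    sigma: float
    cp_rand: float
    lp_rand: float


def _swap_edges(
    edges: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], int]:
    """Double-edge-swap an undirected edge list in place.

    Each accepted swap replaces edges (u,v),(x,y) by (u,x),(v,y), rejecting
    candidates that would create a self-loop or duplicate edge, so the
    degree sequence is invariant and the graph stays simple.
    """
    e = len(edges)
    elist: list[tuple[int, int]] = [
        (int(a), int(b)) if a < b else (int(b), int(a)) for a, b in edges
    ]
    eset = set(elist)
    swaps = tries = 0
    max_tries = max(100 * n_swaps, 1000)
    block = max(4 * n_swaps, 256)
    while swaps < n_swaps and tries < max_tries:
        idx_i = rng.integers(0, e, size=block).tolist()
        idx_j = rng.integers(0, e, size=block).tolist()
        flips = rng.integers(0, 2, size=block).tolist()
        for i, j, flip in zip(idx_i, idx_j, flips):
            tries += 1
            if swaps >= n_swaps or tries >= max_tries:
                break
            if i == j:
                continue
            u, v = elist[i]
            x, y = elist[j]
            if flip:
                x, y = y, x
            if u == x or u == y or v == x or v == y:
                continue
            e1 = (u, x) if u < x else (x, u)
            e2 = (v, y) if v < y else (y, v)
            if e1 in eset or e2 in eset:
                continue
            eset.discard(elist[i])
            eset.discard(elist[j])
            eset.add(e1)
            eset.add(e2)
            elist[i] = e1
            elist[j] = e2
            swaps += 1
    return elist, swaps


def rewire_degree_preserving(
    net: BinaryNetwork, n_swaps_per_edge: int = 10, seed: int = 0
) -> BinaryNetwork:
    """Degree-preserving randomisation by double edge swaps.

    Performs ``n_swaps_per_edge * E`` accepted swaps (or as many as the
    attempt budget allows on near-rigid graphs).  ``n_swaps_per_edge = 0``
    returns an identical copy, the identity null used to validate the
    small-world coefficients.
    """
    edges = net.edges()
    if len(edges) < 2:
        warnings.warn(
            "fewer than 2 edges: no swappable edge pairs; returning the "
            "network unchanged",
            stacklevel=2,
        )
        return _from_edges(net, [tuple(e) for e in edges])
    n_swaps = n_swaps_per_edge * len(edges)
    if n_swaps == 0:
        return _from_edges(net, [tuple(e) for e in edges])
    rng = np.random.default_rng(seed)
    elist, achieved = _swap_edges(edges, n_swaps, rng)
    if achieved == 0:
        warnings.warn(
            "no valid double edge swaps found (rigid degree sequence); "
            "returning the network unchanged",
            stacklevel=2,
        )
    return _from_edges(net, elist)


def _from_edges(net: BinaryNetwork, elist) -> BinaryNetwork:
    n = net.n_regions
    adj = np.zeros((n, n), dtype=np.uint8)
    for a, b in elist:
        adj[a, b] = adj[b, a] = 1
    k = int(adj.sum())
    return BinaryNetwork(
        regions=list(net.regions),
        adjacency=adj,
        density=k / (n * (n - 1)) if n > 1 else 0.0,
        k_nonzero=k,
        requested_density=net.requested_density,
    )


def build_null_ensemble(
    net: BinaryNetwork,
    n_nulls: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> NullEnsemble:
    """Cp and Lp over ``n_nulls`` independent degree-matched rewirings."""
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    ss = np.random.SeedSequence(seed)
    cps, lps = [], []
    for child in ss.spawn(n_nulls):
        null = rewire_degree_preserving(
            net, n_swaps_per_edge, seed=int(child.generate_state(1)[0])
        )
        cps.append(clustering_coefficient(null))
        lps.append(characteristic_path_length(null))
    return NullEnsemble(
        n_nulls=n_nulls, cp_values=np.array(cps), lp_values=np.array(lps)
    )


def small_world_params(
    net: BinaryNetwork,
    n_nulls: int = 100,
    seed: int = 0,
    n_swaps_per_edge: int = 10,
) -> SmallWorldParams:
    """gamma, lambda and sigma against a degree-matched null ensemble."""
    ens = build_null_ensemble(net, n_nulls, n_swaps_per_edge, seed)
    cp = clustering_coefficient(net)
    lp = characteristic_path_length(net)
    if ens.cp_rand == 0 or ens.lp_rand == 0:
        raise ValueError("null ensemble mean Cp or Lp is 0; gamma/lambda undefined")
    gamma = cp / ens.cp_rand
    lam = lp / ens.lp_rand
    return SmallWorldParams(
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        cp_rand=ens.cp_rand,
        lp_rand=ens.lp_rand,
    )
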