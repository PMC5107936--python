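"""Density profiles, AUC summaries and permutation tests for group differences.

Because every graph statistic depends on the arbitrary thresholding density,
each metric is evaluated over the whole density grid and summarised by the
area under its metric-vs-density curve (AUC, trapezoidal rule).  Group
differences in AUC are tested nonparametrically: subjects are reassigned to
the two groups at random (preserving the original group sizes), the *entire*
pipeline (correlation -> thresholding -> metric -> AUC) is recomputed for
each relabeling, and the observed difference is ranked in the resulting
null distribution to give a two-tailed p-value

    p = (1 + #{|null| >= |observed|}) / (n_perm + 1).

Scalar statistics evaluated at a single fixed density (hub betweenness,
robustness outcomes) are tested with the same relabeling scheme via
:func:`permutation_test_scalar`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .construction import (
    BinaryNetwork,
    CorrelationMatrix,
    DensityGrid,
    binarize_over_grid,
    correlation_matrix,
)
from .metrics import (
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    modularity,
    _hop_distances,
)
from .nulls import build_null_ensemble
from .synthetic import CohortTable

__all__ = [
    "METRICS",
    "NullConfig",
    "DensityProfile",
    "PermutationResult",
    "metric_profile",
    "permutation_test_auc",
    "permutation_test_auc_multi",
    "permutation_test_scalar",
    "bonferroni_adjust",
]

#: Supported density-profile metrics.
METRICS = ("cp", "lp", "gamma", "lambda", "sigma", "e_glob", "e_loc", "q")

_SMALL_WORLD = {"gamma", "lambda", "sigma"}


@dataclass(frozen=True)
class NullConfig:
    """Size of the degree-matched null ensemble behind gamma/lambda/sigma."""

    n_nulls: int = 100
    n_swaps_per_edge: int = 10


@dataclass
class DensityProfile:
    """A metric evaluated on the density grid, plus its AUC.

    Densities where the metric is undefined (e.g. Lp on an edgeless
    network) are recorded as NaN and excluded from the AUC.
    """

    metric_name: str
    grid: DensityGrid
    values: np.ndarray
    auc: float


@dataclass
class PermutationResult:
    statistic_name: str
    observed_diff: float
    null_diffs: np.ndarray
    p_two_tailed: float
    n_perm: int
    seed: int


def _auc(values: np.ndarray, grid_values: np.ndarray) -> float:
    """Trapezoidal AUC over the finite points of a profile."""
    values = np.asarray(values, float)
    ok = np.isfinite(values)
    if ok.sum() < 2:
        warnings.warn(
            "fewer than 2 finite profile points; AUC defined as 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.trapezoid(values[ok], np.asarray(grid_values)[ok]))


def network_metric_values(
    net: BinaryNetwork,
    metrics: Iterable[str],
    seed: int = 0,
    null_cfg: NullConfig | None = None,
    n_restarts: int = 20,
) -> dict[str, float]:
    """Evaluate a set of metrics on one network, sharing intermediate work.

    Shortest-path distances are computed once for lp/e_glob, and a single
    null ensemble serves all of gamma/lambda/sigma.  Metrics that are
    undefined on the network (no edges) come back as NaN with a warning.
    """
    metrics = set(metrics)
    unknown = metrics - set(METRICS)
    if unknown:
        raise ValueError(f"unsupported metrics: {sorted(unknown)}")
    null_cfg = null_cfg or NullConfig()
    out: dict[str, float] = {}
    no_edges = net.k_nonzero == 0

    need_dist = metrics & {"lp", "e_glob"}
    dist = _hop_distances(net.adjacency) if need_dist and not no_edges else None

    cp = clustering_coefficient(net) if metrics & ({"cp"} | _SMALL_WORLD) else None
    if "cp" in metrics:
        out["cp"] = cp
    if "lp" in metrics or metrics & _SMALL_WORLD:
        if no_edges:
            warnings.warn("no edges: lp undefined at this density", stacklevel=2)
            lp = np.nan
        else:
            lp = characteristic_path_length(net, _distances=dist)
        if "lp" in metrics:
            out["lp"] = lp
    if "e_glob" in metrics:
        out["e_glob"] = (
            0.0 if no_edges else global_efficiency(net, _distances=dist)
        )
    if "e_loc" in metrics:
        out["e_loc"] = local_efficiency(net)
    if "q" in metrics:
        if no_edges:
            warnings.warn("no edges: q undefined at this density", stacklevel=2)
            out["q"] = np.nan
        else:
            out["q"], _ = modularity(net, seed=seed, n_restarts=n_restarts)
    if metrics & _SMALL_WORLD:
        if no_edges:
            warnings.warn(
                "no edges: small-world parameters undefined", stacklevel=2
            )
            sw = {"gamma": np.nan, "lambda": np.nan, "sigma": np.nan}
        else:
            ens = build_null_ensemble(
                net, null_cfg.n_nulls, null_cfg.n_swaps_per_edge, seed
            )
            gamma = cp / ens.cp_rand if ens.cp_rand > 0 else np.nan
            lam = lp / ens.lp_rand if ens.lp_rand > 0 else np.nan
            sw = {"gamma": gamma, "lambda": lam, "sigma": gamma / lam}
        for k in _SMALL_WORLD & metrics:
            out[k] = sw[k]
    return out


def _group_profiles(
    x: np.ndarray,
    regions: Sequence[str],
    metrics: set[str],
    grid: DensityGrid,
    seed: int,
    null_cfg: NullConfig,
    n_restarts: int,
) -> dict[str, np.ndarray]:
    """Metric profiles over the grid for one group's subject x region data."""
    r = np.clip(np.corrcoef(x, rowvar=False), -1.0, 1.0)
    r = (r + r.T) / 2.0
    R = CorrelationMatrix(regions=list(regions), r=r, n_subjects=x.shape[0])
    nets = binarize_over_grid(R, grid)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(nets))
    values = {m: np.empty(len(nets)) for m in metrics}
    for k, (net, child) in enumerate(zip(nets, children)):
        vals = network_metric_values(
            net,
            metrics,
            seed=int(child.generate_state(1)[0] % (2**31)),
            null_cfg=null_cfg,
            n_restarts=n_restarts,
        )
        for m in metrics:
            values[m][k] = vals[m]
    return values


def metric_profile(
    cohort: CohortTable,
    group: str,
    metric: str,
    grid: DensityGrid | None = None,
    null_cfg: NullConfig | None = None,
    seed: int = 0,
    n_restarts: int = 20,
) -> DensityProfile:
    """correlation -> thresholded networks over the grid -> metric -> AUC."""
    if metric not in METRICS:
        raise ValueError(f"unsupported metric {metric!r}; one of {METRICS}")
    grid = grid or DensityGrid()
    null_cfg = null_cfg or NullConfig()
    # validates group membership / subject counts / variance
    correlation_matrix(cohort, group)
    values = _group_profiles(
        cohort.group_values(group),
        cohort.regions,
        {metric},
        grid,
        seed,
        null_cfg,
        n_restarts,
    )[metric]
    return DensityProfile(
        metric_name=metric,
        grid=grid,
        values=values,
        auc=_auc(values, grid.values),
    )


def _two_tailed_p(observed: np.ndarray, nulls: np.ndarray) -> float:
    """Add-one two-tailed percentile p; ``observed`` may vary per permutation
    when undefined densities are dropped pairwise."""
    count = int(np.sum(np.abs(nulls) >= np.abs(observed)))
    return (1 + count) / (len(nulls) + 1)


def permutation_test_auc_multi(
    cohort: CohortTable,
    metrics: Sequence[str],
    grid: DensityGrid | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    null_cfg: NullConfig | None = None,
    n_restarts: int = 20,
) -> dict[str, PermutationResult]:
    """Subject-relabeling AUC tests for several metrics on shared relabelings.

    One set of ``n_perm`` size-preserving relabelings is drawn and the full
    pipeline is recomputed per relabeling for all requested metrics at once,
    so the per-metric null distributions are comparable and the cost of
    correlation/thresholding is shared.  Densities where a metric is
    undefined in either the observed or a permuted network are dropped
    pairwise from both AUCs of that comparison.
    """
    metrics = list(dict.fromkeys(metrics))
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unsupported metrics: {sorted(unknown)}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable p-value")
    grid = grid or DensityGrid()
    null_cfg = null_cfg or NullConfig()
    group_a, group_b = cohort.groups
    labels = np.asarray(cohort.group_labels)
    mset = set(metrics)

    ss = np.random.SeedSequence(seed)
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    perm_seeds = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_perm + 1)
    ]

    def both_group_values(lbls: np.ndarray, base_seed: int):
        out = {}
        for g_idx, g in enumerate((group_a, group_b)):
            x = cohort.values[lbls == g]
            out[g] = _group_profiles(
                x, cohort.regions, mset, grid, base_seed + g_idx,
                null_cfg, n_restarts,
            )
        return out

    observed = both_group_values(labels, perm_seeds[0])
    perm_values = []
    for k in range(n_perm):
        perm_labels = shuffle_rng.permutation(labels)
        perm_values.append(both_group_values(perm_labels, perm_seeds[k + 1]))

    results: dict[str, PermutationResult] = {}
    for m in metrics:
        obs_a, obs_b = observed[group_a][m], observed[group_b][m]
        obs_valid = np.isfinite(obs_a) & np.isfinite(obs_b)
        obs_k = np.empty(n_perm)
        null_k = np.empty(n_perm)
        for k, pv in enumerate(perm_values):
            pa, pb = pv[group_a][m], pv[group_b][m]
            valid = obs_valid & np.isfinite(pa) & np.isfinite(pb)
            if valid.sum() < 2:
                obs_k[k] = null_k[k] = np.nan
                continue
            g = grid.values[valid]
            obs_k[k] = np.trapezoid(obs_a[valid], g) - np.trapezoid(
                obs_b[valid], g
            )
            null_k[k] = np.trapezoid(pa[valid], g) - np.trapezoid(pb[valid], g)
        ok = np.isfinite(null_k) & np.isfinite(obs_k)
        if not ok.any():
            raise ValueError(
                f"metric {m!r} undefined across the grid in every permutation"
            )
        results[m] = PermutationResult(
            statistic_name=f"auc_{m}",
            observed_diff=_auc(obs_a, grid.values) - _auc(obs_b, grid.values),
            null_diffs=null_k[ok],
            p_two_tailed=_two_tailed_p(obs_k[ok], null_k[ok]),
            n_perm=int(ok.sum()),
            seed=seed,
        )
    return results


def permutation_test_auc(
    cohort: CohortTable,
    metric: str,
    grid: DensityGrid | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    null_cfg: NullConfig | None = None,
    n_restarts: int = 20,
) -> PermutationResult:
    """AUC permutation test for a single metric (group A minus group B)."""
    return permutation_test_auc_multi(
        cohort, [metric], grid, n_perm, seed, null_cfg, n_restarts
    )[metric]


def permutation_test_scalar(
    cohort: CohortTable,
    statistic: Callable[[CohortTable, str], float],
    n_perm: int = 1000,
    seed: int = 0,
    statistic_name: str = "statistic",
) -> PermutationResult:
    """Relabeling test for a scalar statistic (e.g. a region's normalised
    betweenness at the fixed comparison density).

    ``statistic(cohort, group)`` must return a finite scalar; the observed
    and null differences are (group A - group B).
    """
    group_a, group_b = cohort.groups
    labels = np.asarray(cohort.group_labels)
    rng = np.random.default_rng(seed)

    def diff_for(lbls) -> float:
        relabeled = CohortTable(
            subject_ids=list(cohort.subject_ids),
            group_labels=list(lbls),
            regions=list(cohort.regions),
            values=cohort.values,
        )
        return float(
            statistic(relabeled, group_a) - statistic(relabeled, group_b)
        )

    observed = diff_for(labels)
    nulls = np.empty(n_perm)
    for k in range(n_perm):
        nulls[k] = diff_for(rng.permutation(labels))
        if not np.isfinite(nulls[k]):
            raise ValueError(
                f"statistic returned non-finite value at permutation {k}"
            )
    return PermutationResult(
        statistic_name=statistic_name,
        observed_diff=observed,
        null_diffs=nulls,
        p_two_tailed=_two_tailed_p(np.full(n_perm, observed), nulls),
        n_perm=n_perm,
        seed=seed,
    )


def bonferroni_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni correction: min(1, p * m) for a family of m comparisons."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError("family size m must be >= number of p-values")
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    return [min(1.0, p * m) for p in p_values]
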