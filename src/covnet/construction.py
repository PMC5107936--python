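"""Group-level correlation matrices and density-thresholded binary networks.

A structural covariance network is built per *group*: the Pearson
correlation r_ij of regional thickness across that group's subjects defines
edge weights, which are then binarised by keeping only the strongest
strictly-positive correlations until a target connection density is reached.
Density is the fraction K / (N (N - 1)) with K counting both symmetric
nonzero adjacency entries, so the number of undirected edges at density d is
E = round(d N (N - 1) / 2).

Only positive correlations are ever admitted as edges: negative morphometric
correlations are not thought to reflect direct anatomical connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CohortTable

__all__ = [
    "CorrelationMatrix",
    "BinaryNetwork",
    "DensityGrid",
    "correlation_matrix",
    "threshold_at_density",
    "binarize_over_grid",
]


@dataclass
class CorrelationMatrix:
    """Symmetric region x region matrix of Pearson correlations r_ij.

    The diagonal is ignored by all consumers (a region is not connected to
    itself).
    """

    regions: list[str]
    r: np.ndarray
    n_subjects: int

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.regions)
        if self.r.shape != (n, n):
            raise ValueError(f"r must be {n}x{n}, got {self.r.shape}")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        off = ~np.eye(n, dtype=bool)
        if np.any(np.abs(self.r[off]) > 1 + 1e-12):
            raise ValueError("|r_ij| must be <= 1")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.regions, columns=self.regions).to_csv(
            path, sep="\t", index_label="region"
        )


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency A at a stated connection density.

    ``k_nonzero`` is the count of nonzero off-diagonal entries (both
    symmetric entries counted), so
    ``density = k_nonzero / (N (N - 1))``.
    """

    regions: list[str]
    adjacency: np.ndarray
    density: float
    k_nonzero: int
    requested_density: float | None = None
    density_warning: bool = False

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges (k_nonzero / 2)."""
        return self.k_nonzero // 2

    def edges(self) -> np.ndarray:
        """Undirected edge list as an (E, 2) array of region indices, i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])

    def to_edge_list_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("region_a\tregion_b\n")
            for i, j in self.edges():
                fh.write(f"{self.regions[i]}\t{self.regions[j]}\n")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.adjacency, index=self.regions, columns=self.regions
        ).to_csv(path, sep="\t", index_label="region")


@dataclass
class DensityGrid:
    """Inclusive arithmetic grid of connection densities."""

    d_min: float = 0.05
    d_max: float = 0.40
    step: float = 0.01
    values: np.ndarray = field(init=False)

    def __post_init__(self):
        if not (0 < self.d_min <= self.d_max <= 1) or self.step <= 0:
            raise ValueError("need 0 < d_min <= d_max <= 1 and step > 0")
        n = int(round((self.d_max - self.d_min) / self.step)) + 1
        vals = self.d_min + self.step * np.arange(n)
        vals = vals[vals <= self.d_max + 1e-9]
        self.values = np.round(vals, 10)

    def __len__(self) -> int:
        return len(self.values)


def correlation_matrix(cohort: CohortTable, group: str) -> CorrelationMatrix:
    """Pearson correlations of every region pair across one group's subjects."""
    x = cohort.group_values(group)
    if x.shape[0] < 3:
        raise ValueError(
            f"group {group!r} has {x.shape[0]} subjects; need >= 3"
        )
    var = x.var(axis=0)
    if np.any(var == 0):
        zero = [r for r, v in zip(cohort.regions, var) if v == 0]
        raise ValueError(
            f"zero variance within group {group!r} for region(s): {zero}"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(
        regions=list(cohort.regions), r=r, n_subjects=x.shape[0]
    )


def _edge_order(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strictly positive upper-triangle entries sorted by descending r, ties
    broken by (smaller row, smaller column) for reproducibility."""
    n = r.shape[0]
    rows, cols = np.triu_indices(n, 1)
    vals = r[rows, cols]
    pos = vals > 0
    rows, cols, vals = rows[pos], cols[pos], vals[pos]
    order = np.lexsort((cols, rows, -vals))
    return rows[order], cols[order], vals[order]


def threshold_at_density(R: CorrelationMatrix, density: float) -> BinaryNetwork:
    """Binarise a correlation matrix at a target connection density.

    Retains exactly the E = round(density * N (N-1) / 2) strongest strictly
    positive off-diagonal correlations as undirected edges.  If fewer than E
    positive correlations exist, all of them are kept and the network is
    returned at the achievable density with ``density_warning`` set.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = R.n_regions
    e_target = int(round(density * n * (n - 1) / 2))
    rows, cols, _ = _edge_order(R.r)
    short = len(rows) < e_target
    if short:
        warnings.warn(
            f"only {len(rows)} positive correlations available for target "
            f"E={e_target} (density {density:.3g}); returning achievable "
            "density",
            stacklevel=2,
        )
    e = min(e_target, len(rows))
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[rows[:e], cols[:e]] = 1
    adj |= adj.T
    k = int(adj.sum())
    return BinaryNetwork(
        regions=list(R.regions),
        adjacency=adj,
        density=k / (n * (n - 1)),
        k_nonzero=k,
        requested_density=density,
        density_warning=short,
    )


def binarize_over_grid(R: CorrelationMatrix, grid: DensityGrid) -> list[BinaryNetwork]:
    """One binary network per grid density.

    Networks are nested: every density keeps a prefix of the same ranked
    edge list, so the edge set at a lower density is a subset of the edge
    set at any higher density.  The ranking is computed once and shared
    across the grid.
    """
    n = R.n_regions
    rows, cols, _ = _edge_order(R.r)
    nets = []
    for density in grid.values:
        e_target = int(round(density * n * (n - 1) / 2))
        short = len(rows) < e_target
        if short:
            warnings.warn(
                f"only {len(rows)} positive correlations available for "
                f"target E={e_target} (density {density:.3g}); returning "
                "achievable density",
                stacklevel=2,
            )
        e = min(e_target, len(rows))
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[rows[:e], cols[:e]] = 1
        adj |= adj.T
        k = int(adj.sum())
        nets.append(
            BinaryNetwork(
                regions=list(R.regions),
                adjacency=adj,
                density=k / (n * (n - 1)),
                k_nonzero=k,
                requested_density=float(density),
                density_warning=short,
            )
        )
    return nets
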