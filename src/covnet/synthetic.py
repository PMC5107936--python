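"""Synthetic two-group cohorts with known covariance topology.

Real structural-covariance studies start from a subject x region table of a
morphometric measure (here: cortical thickness in mm) and analyse the
*between-subject* correlation structure of the regions.  This module generates
such tables from an explicit target correlation matrix with planted modules,
planted hub regions and a tunable group effect, so that every downstream
stage of the pipeline (thresholding, graph metrics, permutation inference)
can be validated against known ground truth.

The generative model is a multivariate normal per group: region i of subject
s in group g is drawn from N(mu_i, sd_i^2) with corr(region i, region j)
given by a block-structured target matrix (see :class:`CovarianceSpec`).
Normality is an assumption of convenience; real thickness distributions are
only approximately Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovarianceSpec",
    "CohortTable",
    "build_covariance",
    "generate_cohort",
    "demo_specs",
    "DESIKAN_KILLIANY_68",
]

#: The 34 gyral parcels of the Desikan-Killiany atlas, per hemisphere.
_DK_34 = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

#: 68 cortical region names (34 per hemisphere), the standard node set for
#: whole-cortex structural covariance networks.
DESIKAN_KILLIANY_68: tuple[str, ...] = tuple(
    f"{hemi}_{name}" for hemi in ("lh", "rh") for name in _DK_34
)


class CovarianceConstructionError(ValueError):
    """Raised when the PSD repair would distort the target correlations."""


@dataclass(frozen=True)
class CovarianceSpec:
    """Target correlation topology for one group.

    Parameters
    ----------
    partition
        Module label per region (length = number of regions).  Every region
        belongs to exactly one module.
    r_within
        Target correlation between two regions of the same module, in (0, 1).
        ``r_within == 0`` is allowed as the degenerate independent case.
    r_between
        Target correlation between regions of different modules,
        in [0, r_within).
    hub_regions
        Region indices given elevated cross-module correlation ``r_hub``;
        these act as connector hubs in the thresholded network.
    r_hub
        Cross-module correlation for hub regions, in (r_between, 1).
    mean_thickness
        Per-region mean (mm); scalar broadcasts to all regions.
    sd_thickness
        Per-region standard deviation (mm, > 0); scalar broadcasts.
    """

    partition: tuple
    r_within: float
    r_between: float = 0.0
    hub_regions: tuple = ()
    r_hub: float | None = None
    mean_thickness: float | tuple = 2.5
    sd_thickness: float | tuple = 0.15

    def __post_init__(self):
        object.__setattr__(self, "partition", tuple(self.partition))
        object.__setattr__(self, "hub_regions", tuple(self.hub_regions))
        n = self.n_regions
        if n < 2:
            raise ValueError("need at least 2 regions")
        if not (0.0 <= self.r_within < 1.0):
            raise ValueError(f"r_within must be in [0, 1), got {self.r_within}")
        if self.r_within > 0 and not (0.0 <= self.r_between < self.r_within):
            raise ValueError(
                f"r_between must be in [0, r_within), got {self.r_between}"
            )
        if self.hub_regions:
            if self.r_hub is None:
                raise ValueError("hub_regions given but r_hub is None")
            if not (self.r_between < self.r_hub < 1.0):
                raise ValueError(
                    f"r_hub must be in (r_between, 1), got {self.r_hub}"
                )
            if any(not (0 <= i < n) for i in self.hub_regions):
                raise ValueError("hub region index out of range")
        means = np.broadcast_to(np.asarray(self.mean_thickness, float), (n,))
        sds = np.broadcast_to(np.asarray(self.sd_thickness, float), (n,))
        if np.any(sds <= 0):
            raise ValueError("sd_thickness must be > 0")
        object.__setattr__(self, "_means", means.copy())
        object.__setattr__(self, "_sds", sds.copy())

    @property
    def n_regions(self) -> int:
        return len(self.partition)

    @property
    def means(self) -> np.ndarray:
        return self._means

    @property
    def sds(self) -> np.ndarray:
        return self._sds

    @classmethod
    def from_dict(cls, d: dict) -> "CovarianceSpec":
        keys = {
            "partition", "r_within", "r_between", "hub_regions", "r_hub",
            "mean_thickness", "sd_thickness",
        }
        unknown = set(d) - keys
        if unknown:
            raise ValueError(f"unknown CovarianceSpec fields: {sorted(unknown)}")
        d = dict(d)
        for k in ("mean_thickness", "sd_thickness"):
            if isinstance(d.get(k), list):
                d[k] = tuple(d[k])
        return cls(**d)


def _target_matrix(spec: CovarianceSpec) -> np.ndarray:
    """Block-rule target correlations, before any PSD repair."""
    part = np.asarray(spec.partition, dtype=object)
    same = part[:, None] == part[None, :]
    c = np.where(same, spec.r_within, spec.r_between).astype(float)
    if spec.hub_regions:
        hub = np.zeros(spec.n_regions, bool)
        hub[list(spec.hub_regions)] = True
        cross_hub = (hub[:, None] | hub[None, :]) & ~same
        c[cross_hub] = spec.r_hub
    np.fill_diagonal(c, 1.0)
    return c


def build_covariance(spec: CovarianceSpec, repair_tol: float = 0.05) -> np.ndarray:
    """Construct the region x region target correlation matrix of a spec.

    Entry (i, j) is ``r_within`` for regions in the same module, ``r_hub``
    when either region is a planted hub (and the modules differ), and
    ``r_between`` otherwise; the diagonal is 1.  If the block construction is
    not positive semi-definite it is repaired by clipping negative
    eigenvalues to zero, reconstructing, and renormalising the diagonal to 1.

    Raises
    ------
    CovarianceConstructionError
        If the repair moves any entry by more than ``repair_tol``.
    """
    c = _target_matrix(spec)
    vals = np.linalg.eigvalsh(c)
    if vals[0] >= -1e-12:
        return c
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    dev = np.abs(repaired - c)
    worst = np.unravel_index(np.argmax(dev), dev.shape)
    if dev[worst] > repair_tol:
        raise CovarianceConstructionError(
            f"PSD repair moved entry {worst} by {dev[worst]:.4f} "
            f"(> tolerance {repair_tol})"
        )
    return repaired


@dataclass
class CohortTable:
    """Subject x region morphometry table with two group labels.

    The sole external input of the pipeline.  ``values[s, i]`` is the
    thickness (mm) of region ``regions[i]`` in subject ``subject_ids[s]``.
    """

    subject_ids: list[str]
    group_labels: list[str]
    regions: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n_s, n_r = self.values.shape
        if len(self.subject_ids) != n_s or len(self.group_labels) != n_s:
            raise ValueError("subject_ids/group_labels length mismatch")
        if len(self.regions) != n_r:
            raise ValueError("regions length mismatch")
        if len(set(self.subject_ids)) != n_s:
            dup = [s for s in self.subject_ids if self.subject_ids.count(s) > 1]
            raise ValueError(f"duplicated subject IDs: {sorted(set(dup))}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite value at subject {self.subject_ids[bad[0]]},"
                f" region {self.regions[bad[1]]}"
            )
        if len(self.groups) != 2:
            raise ValueError(
                f"expected exactly 2 groups, found {len(self.groups)}: "
                f"{self.groups}"
            )
        var = self.values.var(axis=0)
        if np.any(var == 0):
            zero = [r for r, v in zip(self.regions, var) if v == 0]
            raise ValueError(f"zero-variance region column(s): {zero}")

    @property
    def groups(self) -> list[str]:
        """The distinct group labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g)
        return list(seen)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def group_values(self, group: str) -> np.ndarray:
        """Rows of ``values`` belonging to one group."""
        mask = np.asarray([g == group for g in self.group_labels])
        if not mask.any():
            raise KeyError(f"unknown group {group!r}; have {self.groups}")
        return self.values[mask]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.regions)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "subject", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        """Write as CSV: header ``subject,group,<regions...>``, no index."""
        self.to_frame().to_csv(path, index=False)


def generate_cohort(
    spec_a: CovarianceSpec,
    spec_b: CovarianceSpec,
    n_a: int,
    n_b: int,
    seed: int,
    group_names: tuple[str, str] = ("A", "B"),
    region_names: Sequence[str] | None = None,
) -> CohortTable:
    """Draw a two-group cohort from group-specific covariance structures.

    Group A rows are multivariate normal with correlation
    ``build_covariance(spec_a)`` scaled by its per-region SDs and means;
    likewise group B.  Reproducible under a fixed ``seed``.
    """
    if spec_a.n_regions != spec_b.n_regions:
        raise ValueError(
            f"region count mismatch: {spec_a.n_regions} vs {spec_b.n_regions}"
        )
    if n_a < 3 or n_b < 3:
        raise ValueError("need at least 3 subjects per group")
    n_regions = spec_a.n_regions
    if region_names is None:
        region_names = [f"region_{i + 1:02d}" for i in range(n_regions)]
    elif len(region_names) != n_regions:
        raise ValueError("region_names length mismatch")

    rng = np.random.default_rng(seed)
    blocks, labels, ids = [], [], []
    for spec, n, name in ((spec_a, n_a, group_names[0]),
                          (spec_b, n_b, group_names[1])):
        corr = build_covariance(spec)
        cov = corr * np.outer(spec.sds, spec.sds)
        x = rng.multivariate_normal(spec.means, cov, size=n, method="eigh")
        blocks.append(x)
        labels += [name] * n
        ids += [f"sub-{name}-{i + 1:03d}" for i in range(n)]
    return CohortTable(
        subject_ids=ids,
        group_labels=labels,
        regions=list(region_names),
        values=np.vstack(blocks),
    )


def demo_specs(
    n_regions: int = 68,
    n_modules: int = 4,
    r_within_a: float = 0.40,
    r_within_b: float = 0.50,
    r_between: float = 0.10,
    n_hubs: int = 3,
    r_hub: float = 0.30,
) -> tuple[CovarianceSpec, CovarianceSpec]:
    """Bundled demo: a 'patient'-like spec A with weaker within-module
    covariance than 'control'-like spec B, shared modules and hubs.

    The defaults emulate a whole-cortex study: 68 regions in 4 covariance
    modules, 3 connector-hub regions (one per leading module), and a group
    effect expressed purely through covariance (lower ``r_within`` in group
    A), since all downstream statistics are correlation-based.
    """
    sizes = np.full(n_modules, n_regions // n_modules)
    sizes[: n_regions % n_modules] += 1
    partition = tuple(
        m for m, size in enumerate(sizes) for _ in range(size)
    )
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    hubs = tuple(int(starts[i % n_modules]) for i in range(n_hubs))
    common = dict(
        partition=partition,
        r_between=r_between,
        hub_regions=hubs,
        r_hub=r_hub,
        mean_thickness=2.5,
        sd_thickness=0.15,
    )
    return (
        CovarianceSpec(r_within=r_within_a, **common),
        CovarianceSpec(r_within=r_within_b, **common),
    )
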