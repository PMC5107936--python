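"""End-to-end run orchestration: cohort in, reproducible run directory out.

A run comprises, per group: the correlation matrix, thresholded networks
over the density grid (written as edge lists), density profiles for the
eight network metrics, hub tables at the fixed comparison density, and
four robustness curves; plus a joint subject-relabeling permutation report
covering the AUC of every metric and the normalised betweenness of every
observed hub region.  Every random draw descends from the single config
seed, and a manifest (config + seed + versions) is written so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import networkx
import numpy as np
import pandas as pd
import scipy

from . import __version__
from .construction import (
    DensityGrid,
    binarize_over_grid,
    correlation_matrix,
    threshold_at_density,
)
from .inference import (
    METRICS,
    NullConfig,
    _auc,
    bonferroni_adjust,
    permutation_test_auc_multi,
)
from .metrics import identify_hubs, node_betweenness
from .robustness import random_failure_curve, targeted_attack_curve
from .synthetic import CohortTable

__all__ = ["RunConfig", "read_cohort", "run_pipeline"]

logger = logging.getLogger("covnet")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults follow common practice for group-level covariance networks:
    density grid 0.05-0.40 in steps of 0.01, a fixed comparison density of
    0.19 for hubs and robustness, 1000 permutations and 1000 random-failure
    repetitions.
    """

    input: str | Path
    out: str | Path
    group_column: str = "group"
    subject_column: str = "subject"
    density_min: float = 0.05
    density_max: float = 0.40
    density_step: float = 0.01
    fixed_density: float = 0.19
    n_perm: int = 1000
    n_nulls: int = 100
    n_nulls_perm: int | None = None  # nulls per permutation; defaults to n_nulls
    n_reps: int = 1000
    n_swaps_per_edge: int = 10
    n_restarts: int = 20
    attack_modes: tuple[str, ...] = (
        "random_node",
        "random_edge",
        "targeted_node",
        "targeted_edge",
    )
    seed: int = 0

    @property
    def grid(self) -> DensityGrid:
        return DensityGrid(self.density_min, self.density_max, self.density_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input"] = str(d["input"])
        d["out"] = str(d["out"])
        d["attack_modes"] = list(d["attack_modes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "attack_modes" in d:
            d["attack_modes"] = tuple(d["attack_modes"])
        return cls(**d)


def read_cohort(
    path: str | Path,
    group_column: str = "group",
    subject_column: str = "subject",
) -> CohortTable:
    """Read and validate a subject x region table (CSV or TSV by extension).

    Region order follows the file's column order.  Errors name the
    offending row/column: missing values, non-numeric region cells,
    duplicated subject IDs, or a group count other than 2.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (subject_column, group_column):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    region_cols = [c for c in df.columns if c not in (subject_column, group_column)]
    if len(region_cols) < 2:
        raise ValueError("need at least 2 region columns")
    values = np.empty((len(df), len(region_cols)))
    for j, c in enumerate(region_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value in region column {c!r}, row {row + 2} "
                f"of {path.name}: {df[c].iloc[row]!r}"
            )
        if col.isna().any():
            row = int(np.flatnonzero(col.isna())[0])
            raise ValueError(
                f"missing value in region column {c!r}, row {row + 2} of "
                f"{path.name}"
            )
        values[:, j] = col.to_numpy()
    return CohortTable(
        subject_ids=[str(s) for s in df[subject_column]],
        group_labels=[str(g) for g in df[group_column]],
        regions=region_cols,
        values=values,
    )


def _hub_betweenness_tests(
    cohort: CohortTable,
    regions: list[str],
    fixed_density: float,
    n_perm: int,
    seed: int,
) -> dict:
    """Relabeling tests for the normalised betweenness of several regions,
    sharing one set of relabelings (betweenness is computed once per
    relabeling and group, then read off for every region)."""
    if not regions:
        return {}
    group_a, group_b = cohort.groups
    labels = np.asarray(cohort.group_labels)
    idx = [cohort.regions.index(r) for r in regions]
    rng = np.random.default_rng(seed)

    def nb_diffs(lbls) -> np.ndarray:
        out = []
        for g in (group_a, group_b):
            x = cohort.values[lbls == g]
            r = np.clip(np.corrcoef(x, rowvar=False), -1, 1)
            from .construction import CorrelationMatrix

            R = CorrelationMatrix(list(cohort.regions), (r + r.T) / 2, len(x))
            bc = node_betweenness(threshold_at_density(R, fixed_density))
            mean = bc.mean()
            out.append(bc[idx] / mean if mean > 0 else np.zeros(len(idx)))
        return out[0] - out[1]

    observed = nb_diffs(labels)
    nulls = np.empty((n_perm, len(regions)))
    for k in range(n_perm):
        nulls[k] = nb_diffs(rng.permutation(labels))
    results = {}
    from .inference import PermutationResult, _two_tailed_p

    for j, region in enumerate(regions):
        results[region] = PermutationResult(
            statistic_name=f"normalized_betweenness_{region}",
            observed_diff=float(observed[j]),
            null_diffs=nulls[:, j],
            p_two_tailed=_two_tailed_p(
                np.full(n_perm, observed[j]), nulls[:, j]
            ),
            n_perm=n_perm,
            seed=seed,
        )
    return results


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage on one cohort and write the run directory.

    Returns the output directory.  Identical config (including seed)
    reproduces byte-identical numerical outputs; any stage failure aborts
    with the stage name while preserving the outputs written so far.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.perf_counter()

    def stage(name):
        logger.info("stage: %s", name)
        log_lines.append(f"[{time.perf_counter() - t0:9.2f}s] start {name}")
        return name

    current = "setup"
    grid = config.grid
    null_cfg = NullConfig(config.n_nulls, config.n_swaps_per_edge)
    perm_null_cfg = NullConfig(
        config.n_nulls_perm or config.n_nulls, config.n_swaps_per_edge
    )
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("profiles", "robustness", "permutation"), ss.spawn(3)
        )
    }
    try:
        current = stage("read_cohort")
        cohort = read_cohort(config.input, config.group_column, config.subject_column)
        groups = cohort.groups

        current = stage("correlation_matrices")
        corr = {g: correlation_matrix(cohort, g) for g in groups}
        for g in groups:
            corr[g].to_tsv(out / f"correlation_{g}.tsv")

        current = stage("thresholded_networks")
        nets = {g: binarize_over_grid(corr[g], grid) for g in groups}
        for g in groups:
            edge_dir = out / f"networks_{g}"
            edge_dir.mkdir(exist_ok=True)
            for net in nets[g]:
                net.to_edge_list_tsv(
                    edge_dir / f"edges_density_{net.requested_density:.2f}.tsv"
                )

        current = stage("metric_profiles")
        from .inference import _group_profiles  # shared-work evaluator

        profiles = {}
        for gi, g in enumerate(groups):
            profiles[g] = _group_profiles(
                cohort.group_values(g),
                cohort.regions,
                set(METRICS),
                grid,
                seeds["profiles"] + gi,
                null_cfg,
                config.n_restarts,
            )
            df = pd.DataFrame({"density": grid.values})
            for m in METRICS:
                df[m] = profiles[g][m]
            df.to_csv(out / f"profiles_{g}.tsv", sep="\t", index=False)

        current = stage("hub_tables")
        fixed_nets = {
            g: threshold_at_density(corr[g], config.fixed_density) for g in groups
        }
        hub_tables = {g: identify_hubs(fixed_nets[g]) for g in groups}
        for g in groups:
            hub_tables[g].to_csv(out / f"hubs_{g}.tsv", sep="\t", index=False)

        current = stage("robustness")
        rob_ss = np.random.SeedSequence(seeds["robustness"])
        rob_children = iter(rob_ss.spawn(len(groups) * len(config.attack_modes)))
        for g in groups:
            for mode in config.attack_modes:
                kind, what = mode.split("_")
                child_seed = int(next(rob_children).generate_state(1)[0])
                if kind == "random":
                    curve = random_failure_curve(
                        fixed_nets[g], what, config.n_reps, seed=child_seed
                    )
                else:
                    curve = targeted_attack_curve(fixed_nets[g], what)
                curve.to_tsv(out / f"robustness_{mode}_{g}.tsv")

        current = stage("permutation_tests")
        auc_results = permutation_test_auc_multi(
            cohort,
            list(METRICS),
            grid,
            n_perm=config.n_perm,
            seed=seeds["permutation"],
            null_cfg=perm_null_cfg,
            n_restarts=config.n_restarts,
        )
        raw_p = [auc_results[m].p_two_tailed for m in METRICS]
        adj_p = bonferroni_adjust(raw_p, len(METRICS))

        current = stage("hub_permutation_tests")
        hub_union = sorted(
            set(hub_tables[groups[0]].query("is_hub").region)
            | set(hub_tables[groups[1]].query("is_hub").region)
        )
        hub_p = _hub_betweenness_tests(
            cohort,
            hub_union,
            config.fixed_density,
            n_perm=config.n_perm,
            seed=seeds["permutation"] + 1,
        )

        current = stage("report")
        report = {
            "groups": groups,
            "n_subjects": {g: int(np.sum(np.asarray(cohort.group_labels) == g))
                           for g in groups},
            "n_regions": cohort.n_regions,
            "metrics": {
                m: {
                    "auc": {g: _auc(profiles[g][m], grid.values) for g in groups},
                    "observed_diff": auc_results[m].observed_diff,
                    "p_raw": auc_results[m].p_two_tailed,
                    "p_bonferroni": adj_p[i],
                    "n_perm": auc_results[m].n_perm,
                }
                for i, m in enumerate(METRICS)
            },
            "hubs": {
                g: hub_tables[g].query("is_hub")["region"].tolist() for g in groups
            },
            "hub_betweenness_tests": {
                region: {
                    "observed_diff": hub_p[region].observed_diff,
                    "p_raw": hub_p[region].p_two_tailed,
                }
                for region in hub_union
            },
            "fixed_density": config.fixed_density,
            "seed": config.seed,
        }
        _write_json(out / "report.json", report)

        tsv_rows = []
        for i, m in enumerate(METRICS):
            tsv_rows.append(
                {
                    "metric": m,
                    **{f"auc_{g}": report["metrics"][m]["auc"][g] for g in groups},
                    "observed_diff": report["metrics"][m]["observed_diff"],
                    "p_raw": raw_p[i],
                    "p_bonferroni": adj_p[i],
                    "n_perm": report["metrics"][m]["n_perm"],
                }
            )
        pd.DataFrame(tsv_rows).to_csv(out / "report.tsv", sep="\t", index=False)

        current = stage("manifest")
        _write_json(
            out / "manifest.json",
            {
                "config": config.to_dict(),
                "versions": {
                    "covnet": __version__,
                    "python": sys.version.split()[0],
                    "numpy": np.__version__,
                    "scipy": scipy.__version__,
                    "pandas": pd.__version__,
                    "networkx": networkx.__version__,
                },
            },
        )
    except Exception as err:
        log_lines.append(
            f"[{time.perf_counter() - t0:9.2f}s] FAILED in stage {current}: {err}"
        )
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed in stage {current!r}: {err}") from err

    log_lines.append(f"[{time.perf_counter() - t0:9.2f}s] done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
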