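# Methods

## The model

`covnet` analyses *group-level* structural covariance networks. The nodes
are cortical regions (68 Desikan–Killiany gyral parcels in the bundled
demo); the connectivity between regions i and j within a group is the
Pearson correlation r_ij of regional thickness across that group's
subjects. The correlation matrix is binarised by rank: at connection
density d on N regions, the E = round(d·N(N−1)/2) largest strictly positive
off-diagonal correlations become undirected, unweighted edges. Density is
defined as K/(N(N−1)) with K counting both symmetric nonzero adjacency
entries, which makes the printed formula and the undirected edge count
consistent. Negative and zero correlations are never admitted, even if the
requested density cannot otherwise be reached (the network is then returned
at the achievable density with a warning flag): negative morphometric
correlations are not considered evidence of direct anatomical connection.
Ties at the threshold break deterministically by (smaller row, smaller
column). Because both groups are thresholded to the same edge count at each
grid point, group differences reflect topology, not overall correlation
level.

## Graph measures and their conventions

All measures operate on the binary adjacency. Where a convention is needed
(the definitions do not cover disconnected or degenerate cases), the
package uses:

* **Clustering coefficient Cp** — mean over nodes of 2t_i/(k_i(k_i−1));
  nodes of degree < 2 contribute 0 rather than being dropped, keeping the
  denominator fixed across groups.
* **Characteristic path length Lp** — mean shortest-path hop count over
  mutually reachable pairs only. This keeps Lp finite at the sparse (5%)
  end of the grid, where networks are usually fragmented.
* **Global efficiency** — mean of 1/d_ij over ordered distinct pairs with
  1/∞ = 0, handling disconnection natively.
* **Local efficiency** — mean over nodes of the global efficiency of the
  subgraph induced on each node's neighbours; nodes with < 2 neighbours
  contribute 0.
* **Small-world coefficients** — γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩,
  σ = γ/λ, with the reference ensemble built by Maslov–Sneppen double edge
  swaps (degree sequence preserved exactly; no self-loops or multi-edges).
  Defaults: 10 accepted swaps per edge, 100 nulls per (group × density).
  Nulls inherit the node set; Lp on nulls uses the same reachable-pair
  convention. The ensemble size is a configuration knob because no single
  null recipe is canonical; doubling it changes ⟨Cp_rand⟩ and ⟨Lp_rand⟩ by
  well under 2% at connectome scale.
* **Modularity Q** — Newman–Girvan Q = Σ_c (e_c/m − (d_c/2m)²), with the
  partition found by seeded Louvain runs (20 restarts by default, best Q
  kept). Q is recomputed from the formula on the returned partition, so
  the reported value never depends on the optimiser's internal objective.
  No constraint is placed on the number of modules.
* **Betweenness / hubs** — Brandes shortest-path betweenness, endpoints
  excluded, each unordered pair counted once, unnormalised internally. The
  hub table reports betweenness divided by the network mean ("normalised
  betweenness"); a node is a hub iff this exceeds 2.
* **Robustness** — relative size of the largest connected component
  (divided by the *total* region count) as a function of the fraction of
  nodes/edges removed. Random failures average 1000 repetitions by
  default; targeted attacks remove in decreasing betweenness order, ranked
  once on the intact network (static order). Adaptive re-ranking after
  each removal is available (`recompute=True`) but not the default, since
  a fixed order is the plain reading of "in decreasing order of their
  betweenness" and is far cheaper. Removal fractions default to a 0–1 grid
  in steps of 0.05.

## Inference

Each metric's density profile (default grid 0.05–0.40, step 0.01) is
summarised by its trapezoidal AUC; densities where a metric is undefined
(e.g. Lp on an edgeless network) are excluded, and when a density is
undefined in either the observed or a permuted network it is dropped
pairwise from both AUCs of that comparison. Group differences use
subject-relabeling permutation tests: relabelings preserve the original
group sizes, the full pipeline is recomputed per relabeling, and the
two-tailed p-value uses the add-one formula (1 + #{|null| ≥ |observed|}) /
(n_perm + 1), which cannot return 0. Default n_perm = 1000. One shared set
of relabelings serves all eight metrics in a pipeline run; within-
permutation null ensembles for γ/λ/σ use per-permutation derived seeds
(their size defaults to `n_nulls` and can be reduced via `n_nulls_perm` —
small ensembles add Monte-Carlo noise to the permutation distribution of
γ/λ/σ symmetrically under the null, at substantial cost savings). Scalar
statistics evaluated at the fixed 19% density (per-hub normalised
betweenness; robustness outcomes) use the same relabeling scheme. The
report carries both raw and Bonferroni-adjusted p-values across the eight
metrics; no other multiplicity correction is applied.

## The synthetic cohort generator

The generator emulates what the pipeline consumes — a two-group subject ×
region thickness table — from an explicit target correlation matrix:
r_within inside planted modules, r_between across them, and r_hub between
planted connector-hub regions and everything outside their module. The
block matrix is repaired to positive semi-definiteness by eigenvalue
clipping and diagonal renormalisation; construction fails if the repair
moves any entry by more than 0.05, so the sampled topology always stays
close to the nominal one. Rows are drawn i.i.d. multivariate normal with
per-region means (2.5 mm) and SDs (0.15 mm) typical of adult cortical
thickness.

Group effects are expressed through covariance (e.g. lower r_within in the
"patient" spec), not mean shifts, because every downstream statistic is
correlation-based. The demo study uses 43 vs 73 subjects, 68 regions in 4
equal covariance modules, r_within 0.40 (patient) vs 0.50 (control),
r_between 0.10, and 3 connector hubs at r_hub 0.30 — values in the range
reported for cortical-thickness covariance, with the hub strength capped
by the PSD-repair tolerance. Weakening within-module covariance lowers the
segregation measures (Cp, local efficiency, Q, γ, σ) and, by spreading
supra-threshold edges across modules, *raises* global efficiency — so the
demo's e_glob contrast runs opposite to its segregation contrast; both
directions are real consequences of the generative model.

What the generator does **not** emulate: non-Gaussian thickness
distributions, site/age/sex covariates, spatial autocorrelation of
neighbouring parcels, and hemispheric asymmetries. Tests passing on
synthetic cohorts therefore validate the pipeline's correctness and
statistical calibration, not any claim about real clinical populations.

## Numerical and scaling choices

* Shortest-path distances use a vectorised boolean-matmul BFS for networks
  up to 256 nodes (faster than sparse Dijkstra at connectome scale, bit-
  identical results), falling back to scipy's csgraph above that.
* All randomness descends from a single seed per entry point via
  `numpy.random.SeedSequence` spawning; identical config ⇒ byte-identical
  outputs. No global RNG state is touched.
* The test-suite simulations and the acceptance script run at reduced
  scale — density grid step 0.05 (8 points), 100–200 permutations, null
  ensembles of 3–25, 100–200 robustness repetitions, 20-region cohorts for
  repeated-study simulations — chosen so the full validation completes on
  a laptop-class single core while keeping every Monte-Carlo margin wide
  relative to the quantities asserted. Defaults in `RunConfig` remain at
  full scale (grid step 0.01, 1000 permutations, 1000 repetitions).

## Known limitations

* Group-level networks yield one network per group; subject-level
  covariates cannot be regressed out, and no parametric alternatives are
  offered.
* Only binary, undirected networks; no weighted or partial-correlation
  variants.
* Louvain is a heuristic: on near-degenerate modularity landscapes the
  best-of-restarts Q retains a small optimiser variance that is folded
  into the permutation null (the same optimiser runs inside every
  permutation).
* The permutation test for γ/λ/σ inherits Monte-Carlo noise from the null
  ensembles; for publication-grade p-values on those metrics, use
  `n_nulls_perm` equal to `n_nulls`.
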