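# covnet

Group-level **structural covariance network** analysis for cortical
morphometry, with a synthetic cohort generator for validation.

In a structural covariance study, the "connectivity" between two cortical
regions is the Pearson correlation of a morphometric measure — here cortical
thickness — across the subjects of a group. `covnet` takes a subject × region
thickness table with two group labels (e.g. patients vs controls) and, per
group:

1. builds the region × region correlation matrix **R** (entries *r<sub>ij</sub>*);
2. binarises it at a series of connection densities, keeping only the
   strongest strictly *positive* correlations: at density *d* on *N* regions,
   exactly E = round(*d·N(N−1)/2*) undirected edges, so density =
   K/(N(N−1)) with K counting both symmetric adjacency entries;
3. computes, at every density on the grid (default 5–40% in steps of 1%):
   clustering coefficient *Cp*, characteristic path length *Lp*, the
   small-world coefficients γ = Cp/⟨Cp<sub>rand</sub>⟩,
   λ = Lp/⟨Lp<sub>rand</sub>⟩ and σ = γ/λ against degree-matched
   (Maslov–Sneppen) rewired null networks, global and local efficiency, and
   Newman–Girvan modularity *Q*;
4. detects **hubs** at a fixed comparison density (default 19%): nodes whose
   betweenness centrality exceeds twice the network mean;
5. measures **robustness**: the relative size of the largest connected
   component as nodes or edges are removed at random (mean over many
   repetitions) or in decreasing order of betweenness (targeted attack);
6. tests group differences nonparametrically: each metric's density profile
   is summarised by its area under the curve (AUC), subjects are relabelled
   at random preserving group sizes, the *entire* pipeline is recomputed per
   relabeling, and the observed AUC difference is ranked in the null
   distribution (two-tailed, add-one p-value), with Bonferroni adjustment
   across the eight metrics.

Because real clinical cohorts of this kind are typically not public, the
`synthetic` module generates two-group cohorts from explicit covariance
structures (planted modules, planted connector hubs, group effects expressed
through covariance), giving every downstream stage a known ground truth.

## Worked example

Simulate the bundled demo study (43 "patient" vs 73 "control" subjects,
68 Desikan–Killiany regions, weaker within-module covariance in patients)
and run a reduced analysis:

```sh
covnet simulate --demo --n-a 43 --n-b 73 --seed 7 --out cohort.csv
covnet run --input cohort.csv --density-step 0.05 --n-perm 100 \
           --n-nulls 25 --n-nulls-perm 3 --n-reps 100 --n-restarts 5 \
           --seed 17 --out results/demo
```

The run directory contains per-group correlation matrices, per-density edge
lists, metric density profiles, hub tables, robustness curves, a permutation
report (`report.json`/`report.tsv`) and a manifest that reproduces the run
exactly. For this seed the report shows, per group (AUC over densities
0.05–0.40, patient vs control):

| metric | patient | control | p (raw) |
|--------|---------|---------|---------|
| σ (small-world) | 0.62 | 1.23 | 0.010 |
| γ | 0.70 | 1.13 | 0.010 |
| Cp | 0.19 | 0.26 | 0.010 |
| local efficiency | 0.25 | 0.28 | 0.010 |
| modularity Q | 0.15 | 0.22 | 0.010 |

Both groups are small-world (σ > 1 across most of the grid), but the
patient group — generated with weaker within-module covariance — shows
reduced clustering, local efficiency, modularity and small-worldness, and
its hub set only partially overlaps the control group's, mirroring the kind
of group contrast this pipeline is designed to detect.

## Library use

```python
from covnet import (demo_specs, generate_cohort, correlation_matrix,
                    threshold_at_density, small_world_params, identify_hubs)

spec_patient, spec_control = demo_specs()
cohort = generate_cohort(spec_patient, spec_control, 43, 73, seed=7,
                         group_names=("patient", "control"))
net = threshold_at_density(correlation_matrix(cohort, "control"), 0.19)
print(net.n_edges)                       # 433 = round(0.19 * 68 * 67 / 2)
print(small_world_params(net, n_nulls=100, seed=0).sigma)
print(identify_hubs(net).head())
```

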