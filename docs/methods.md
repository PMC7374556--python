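# Methods

## The model

`petnet` analyzes *metabolic covariance networks*: group-level graphs in
which node *i* is an atlas ROI and the edge weight between *i* and *j* is
the Pearson correlation, across the subjects of one group, of the two
ROIs' SUVR values after nuisance covariates have been regressed out. The
approach assumes (a) SUVR is comparable across subjects after division by
the whole-cerebellum reference, (b) age and sex act approximately linearly
and additively on regional SUVR, and (c) the subjects of a group are
exchangeable draws from one population — the same exchangeability the
permutation test relies on.

"Correlation controlling for age and gender" is implemented as pairwise
Pearson correlation of covariate-residualized ROI values. It is *not* the
full inverse-covariance partial correlation among all ROIs: with tens of
subjects and ~109 regions the precision matrix is not identifiable, and
the group-covariance convention in this field is the pairwise residual
correlation. No inverse-covariance mode is provided. Residualization is
fitted within each group by default (each group's network is built
independently); a pooled fit over both groups is available via
`RunConfig.pooled_residualization` because the alternative reading is
defensible and cheap to expose.

## Pipeline stages and their parameters

| parameter | default | units | why |
|---|---|---|---|
| `covariates` | `["age", "sex"]` | years; M/F indicator | the standard nuisance pair for PET covariance work; sex is a single 0/1 column, multi-level covariates are rejected |
| `density` | 0.5 | fraction of possible edges | "density 50" convention; fixing density equalizes edge counts across groups so topology, not edge count, is compared |
| `n_perm` | 1000 | count | conventional permutation depth; p-resolution 1/(n+1) ≈ 0.001 |
| `n_null_sigma` | 20 | graphs | enough to stabilize the C and L null means for σ without dominating runtime |
| `modularity_restarts` | 10 | restarts | Louvain is greedy; restarts with distinct seeds and best-Q selection reduce local-optimum noise |
| `q_threshold` | 0.05 | fraction | FDR level for nodal flags |

Negative residual correlations are zeroed before thresholding (their count
is logged — at density 0.5 on real cohorts they are typically absent, but
synthetic nulls can produce them, and the log is the audit trail).
Thresholding keeps exactly `floor(density · R(R−1)/2)` of the strongest
positive edges; ties at the cut are broken by ascending (i, j) node index,
a deterministic rule chosen so that permutation resampling can never
produce two different graphs from identical weights. If fewer positive
weights exist than the target edge count the build fails and reports the
achievable density rather than silently under-filling the graph.

## Graph measures

All topology measures are computed on the **binary** thresholded graph;
average strength alone sums retained correlation weights. A non-default
weighted mode computes distance-based measures on edge lengths 1/w,
Onnela-style clustering, and weighted Q, while assortativity, σ and
betweenness remain binary.

Conventions for degenerate inputs, chosen to match common practice:

- Disconnected node pairs are excluded from the characteristic path length
  (their count is logged) and contribute zero to efficiency.
- Nodes with fewer than two neighbours contribute zero to clustering and
  local efficiency.
- Assortativity is undefined on regular graphs (zero degree variance at
  edge endpoints) and σ is undefined when the rewired nulls have zero mean
  clustering; the single-measure functions raise, while the aggregated
  `metric_set` records NaN for these and computes the rest, so that e.g. a
  complete test graph still yields its closed-form L, E and C.
- Modularity of an edgeless graph is an error; a single-community
  partition is the floor (Q is never reported below 0).

Modularity partition search uses exact maximization (integer programming)
for graphs of ≤ 12 nodes, where it is instantaneous, and seeded Louvain
with best-of-10 restarts above. Louvain is a greedy heuristic and
occasionally misses the optimum even on 8-node graphs; exact search where
feasible removes that failure mode and any seed dependence at validation
scale. The Q value of a partition is always recomputed internally with the
Newman–Girvan formula, regardless of which search produced the partition.

Small-worldness uses σ-type normalization, σ = (C/C̄_null)/(L/L̄_null),
against degree-preserving double-edge-swap nulls (10 swap attempts per
edge per null). If a graph cannot be rewired at all, an Erdős–Rényi graph
with the same node and edge count replaces the null and the fallback is
logged. Betweenness is Brandes' shortest-path betweenness normalized by
(R−1)(R−2)/2, so hub scores are comparable across graph sizes.

## Permutation inference

The null is subject exchangeability: subjects are reassigned to two groups
of the original sizes uniformly at random, covariates travelling with
their subjects, and the **entire** pipeline — residualization refit within
each permuted group, correlation, zeroing, thresholding, measure — is
re-run per permutation. Two-sided p-values use the add-one estimator
`(1 + #{|null| ≥ |obs|})/(n_perm + 1)`: the raw fraction-exceeding
estimator can return exactly zero, which overstates what a finite
permutation sample can establish. The reported interval per measure is the
(2.5, 97.5) percentile interval of the null difference distribution.

Because density is fixed, the binary edge count — and with it average
degree — is identical in every permutation; its null distribution is
degenerate and the package warns when such a measure is tested. All nodal
betweenness tests are driven by one shared permutation stream (not
redrawn per node) for coherence and speed, then BH-FDR corrected across
ROIs. Permutation p-values are discrete with a floor of 1/(n_perm+1), so
with moderate permutation counts the BH step-up is conservative at the
smallest ranks; the nodal null simulations reflect that conservatism.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
each subject's SUVR vector is multivariate normal with a block-constant
correlation matrix (`rho_within` inside contiguous modules, `rho_between`
elsewhere), scaled by `subject_noise_sd`, centered at `mean_suvr`, with an
additive age slope (relative to mid-range age) and sex offset applied
identically to every ROI. Identical additive confounds across ROIs are
deliberate: OLS residualization then removes them exactly in expectation,
which isolates the covariate-control stage for testing. Group B's
within/between contrast is shifted by `delta_contrast_groupB` (±d/2 on the
two rhos, so the contrast moves by exactly d). Defaults: 17 vs 39
subjects, 109 ROIs, 4 modules, rho 0.5/0.2, mean SUVR 1.2, noise SD 0.15,
age slope −0.002/year over ages 20–60, sex offset 0.02 — values a PET
covariance study would recognize as plausible; the injected contrast used
in the validation studies (d = −0.2, i.e. group A more modular) is chosen
for test power, since no effect-size calibration against clinical cohorts
is possible. Block matrices are positive definite by construction for
valid rho orderings; any user-forced violation is repaired by eigenvalue
clipping at 1e-8 and the repair logged.

What the generator does **not** emulate: voxel-level PET noise, scanner
and reconstruction effects, partial-volume artifacts, spatially varying
age effects, or non-Gaussian uptake distributions. Passing tests therefore
demonstrate that the pipeline's statistics behave correctly under the
model's own assumptions, not that those assumptions hold in any given
clinical dataset.

An interaction worth knowing when designing simulations: with
block-constant structure, both groups' thresholded graphs converge to the
*same* topology as n → ∞ (all within-module edges rank above the tied
between-module edges in both groups), so the binary-modularity group
difference is largest at intermediate sampling noise and vanishes
asymptotically. Power across n ∈ {20, 60, 150} per group is monotone for
the d = −0.2 contrast used here, but decays at much larger n.

## Validation studies and problem sizes

The test suite validates every measure against independent brute-force
oracles (Floyd–Warshall paths, triangle counting, exhaustive partition
search over all Bell(n) partitions, all-geodesic betweenness enumeration)
on 200 random graphs of ≤ 8 nodes, exactly to 1e-10. Calibration of the
global permutation test uses 200 replicate null pairs (25 subjects/group,
60 ROIs, 200 permutations), with the rejection count checked against the
exact binomial 95% interval at α = 0.05. Effect recovery uses 50
replicates at 60 subjects/group and a 20-replicate power curve at n ∈
{20, 60, 150}. Nodal FDR behaviour uses 20 null replicates at 15
subjects/group, 30 ROIs. These sizes keep the full suite around ten
minutes on one CPU while leaving each binomial check adequately powered.

## SUVR extraction

Per-ROI SUV is the unweighted arithmetic mean of finite voxels carrying
the ROI's label; the reference mean is computed identically over the
cerebellar label set; SUVR divides elementwise. NaN voxels (outside the
brain mask) are excluded. No partial-volume correction is applied, and
registration to the atlas grid is upstream of this package — only grid
compatibility is checked. The shipped 109-ROI label table is a
reconstruction (48 bilateral cortical regions, 6 bilateral subcortical
structures, brainstem) with left/right cerebellum as reference labels;
any atlas/table pair with the same schema can replace it.

## Known limitations

- Group-level networks only: per-subject metabolic graphs are not defined
  by this covariance construction and are out of scope, as are multi-density
  (area-under-curve) analyses and three-group omnibus tests.
- The permutation engine re-runs the full pipeline per permutation;
  σ-bearing comparisons at 1000 permutations on 109 ROIs take minutes, and
  the per-measure API (`permutation_test`) is the cheap route when only
  one measure is of interest.
- Permutation p-values are discrete; with few permutations the FDR step is
  conservative at small p.
- The weighted mode's σ carries observed weights onto rewired topologies
  by rank assignment, a pragmatic null rather than a principled weighted
  rewiring.
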