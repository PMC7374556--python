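# petnet

Group-level **metabolic covariance network** analysis for FDG-PET.

In FDG-PET covariance analysis, brain connectivity is not measured within a
subject (one static PET image has no time series); instead, the
*between-subject* covariance of regional glucose uptake defines a
group-level network. Regions whose standardized uptake value ratios (SUVR)
rise and fall together across the subjects of a group are treated as
connected. Comparing the graph topology of such networks between clinical
groups — e.g. epilepsy patients with hippocampal sclerosis versus controls
— asks whether a condition reorganizes the brain's metabolic architecture,
not merely its regional uptake levels.

`petnet` implements that pipeline end to end, for neuroimaging researchers
who have per-subject ROI uptake tables (or spatially normalized PET volumes
plus a label atlas) and want reproducible, permutation-based group
inference:

1. **SUVR extraction** — per-ROI mean SUV from a PET volume under an
   integer-label atlas, divided by the whole-cerebellum reference mean:
   `SUVR = SUV_ROI / SUV_cerebellum`.
2. **Network build** — within each group, every ROI's SUVR is residualized
   on age and sex (OLS); edge weights are pairwise Pearson correlations of
   the residuals across subjects; negative correlations are set to zero;
   the matrix is binarized by keeping the strongest edges up to a fixed
   **density** (default 50% of possible edges), so compared groups always
   have identical edge counts.
3. **Graph measures** — average degree *k* and strength *s*,
   characteristic path length *L*, global efficiency *E_glob*, local
   efficiency *E_loc*, mean clustering coefficient *C*, modularity *Q*
   (Newman–Girvan, best partition over seeded searches), degree
   assortativity *r*, small-worldness *σ = (C/C_rand)/(L/L_rand)* against
   degree-preserving rewired nulls, and nodal betweenness centrality *BC*.
4. **Group inference** — subjects (with covariates) are permuted between
   groups and the whole pipeline re-run per permutation; two-sided
   p-values use the add-one estimator `(1 + #{|null| ≥ |obs|})/(n_perm+1)`
   with a 1000-permutation default; nodal betweenness tests share one
   permutation stream and are corrected with Benjamini–Hochberg FDR at
   q < 0.05.

A synthetic-cohort generator (`petnet.synthetic`) produces two-group
cohorts with block-modular correlation structure, age/sex confounds and a
controllable between-group modular contrast, so the entire pipeline is
testable without clinical data.

## Worked example

Simulate a study-sized cohort (17 vs 39 subjects, 109 ROIs) in which group
A carries a stronger modular contrast, then run the full comparison:

```bash
petnet simulate --out cohort.csv --seed 7 --n-per-group 17 39 --delta-contrast -0.2
petnet run --cohort cohort.csv --config cfg.json --out results   # n_perm=200 here
```

The `global.csv` table from that run (values per group, observed
difference B−A, permutation p):

```
average_degree                54.0000  54.0000  +0.0000  p=1.0000
average_strength              29.4523  19.3343 -10.1180  p=0.0846
characteristic_path_length     1.5046   1.5012  -0.0034  p=0.3134
global_efficiency              0.7492   0.7498  +0.0006  p=0.3085
local_efficiency               0.8425   0.8197  -0.0228  p=0.0945
mean_clustering                0.6851   0.6394  -0.0457  p=0.0945
modularity                     0.1672   0.1352  -0.0319  p=0.2836
assortativity                  0.0957   0.0517  -0.0440  p=0.5622
small_worldness                1.1324   1.0837  -0.0487  p=0.1045
```

Reading it: average degree is pinned at 2·⌊0.5·109·108/2⌋/109 = 54 by the
density threshold, so its permutation distribution is degenerate and its
p-value uninformative (the run log warns about this). Group A's network is
more modular (Q 0.167 vs 0.135) with the injected sign, but at 17-vs-39
subjects the permutation test does not reach significance — a faithful
picture of how little power small PET cohorts carry; at 60 subjects per
group the same contrast is detected in essentially every replicate (see
the power quantities below). No nodal betweenness difference survives FDR
here.

The same analysis is available as a library:

```python
from petnet import CohortSpec, simulate_cohort, RunConfig, permutation_test

cohort = simulate_cohort(CohortSpec(n_subjects_per_group=(60, 60), n_rois=60,
                                    n_modules=4, delta_contrast_groupB=-0.2, seed=1))
res = permutation_test(cohort.select_group("A"), cohort.select_group("B"),
                       "modularity", n_perm=1000, seed=1, config=RunConfig())
print(res.observed_difference, res.p_value)
```

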