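# hubdisrupt

Group analysis of weighted structural brain connectomes, built around the
**hub-disruption index**: a whole-brain summary of how a patient group's
nodal network topology is reorganized relative to healthy controls.

The package targets case–control studies (the motivating use case is primary
open-angle glaucoma, POAG, versus healthy controls) where each subject is
represented by a symmetric, non-negative weighted adjacency matrix over a
fixed parcellation — by default the 84-region Desikan cortical + subcortical
scheme — typically derived from diffusion tractography. Tractography itself
is out of scope: the input to this package *is* the adjacency matrix.

## What it computes

1. **Proportional thresholding.** Each subject's matrix is thresholded at a
   sparsity of 10%: the K = ⌊0.10 · N(N−1)/2⌋ strongest edges are kept with
   their weights (348 edges for N = 84), so all subjects have equal density.
2. **Graph metrics** (Brain Connectivity Toolbox conventions, weighted,
   implemented from first principles): nodal strength
   s<sub>i</sub> = Σ<sub>j</sub> w<sub>ij</sub>, Onnela clustering
   coefficient, betweenness centrality on edge lengths 1/w, local efficiency
   on neighborhood subgraphs, global efficiency, transitivity, and
   per-subject global means.
3. **Hub-disruption index.** For a nodal metric LM with control-mean profile
   ⟨LM⟩<sub>C</sub> over regions i = 1…N, the subject-wise index k of
   subject S is the OLS slope of

   LM<sub>i,S</sub> − ⟨LM<sub>i</sub>⟩<sub>C</sub> = k0 + k · ⟨LM<sub>i</sub>⟩<sub>C</sub> + ε<sub>i</sub>

   and the group-wise index replaces LM<sub>S</sub> with the patient-group
   mean profile (slope significance: two-sided t-test, N − 2 df). k ≠ 0
   means regions that are strong in controls are systematically
   strengthened (k > 0) or weakened (k < 0) in patients.
4. **Hubs.** A region is a hub for a subject when its metric exceeds 1.5×
   that subject's whole-brain mean; hub presence is compared across groups
   with two-sided Fisher exact tests (exact rational enumeration).
5. **Statistics.** Mann–Whitney U group comparisons (exact enumeration at
   small n, tie-corrected normal approximation otherwise), median-percent
   effect sizes, Benjamini–Hochberg FDR within the appropriate family
   (across regions, within metric), age/sex-adjusted linear models with
   Cohen's f² for clinical associations (VFI, RNFL, GCL, …), and
   single-predictor logistic-regression ROC curves with Youden-index
   operating points (sensitivity, specificity, PPV, NPV, accuracy).
6. **Synthetic cohorts.** Because such MRI datasets are rarely deposited,
   `hubdisrupt.synthetic` generates cohorts with the assumed statistical
   structure — distance-dependent log-normal base connectome, multiplicative
   group effects on edges of designated "affected" regions, a planted
   disruption slope on the strength profile, subject-level multiplicative
   edge noise, and clinical scores tied to a designated region — so every
   stage of the pipeline is testable against known ground truth.

## Worked example

Simulate the default study-sized cohort (15 controls, 23 POAG-like patients,
84 regions, affected occipital/paracentral regions amplified ×1.3, planted
strength-disruption slope 0.16) and run the full analysis:

```bash
hubdisrupt simulate --seed 1 --out demo
hubdisrupt disrupt demo --out report
```

prints the group-wise disruption indices (one per nodal metric):

```
  strength: k = 0.147 (p = 6.85e-05)
  betweenness: k = -0.064 (p = 4.99e-02)
  clustering: k = -0.004 (p = 8.98e-01)
  local_efficiency: k = -0.020 (p = 5.20e-01)
```

The planted slope of 0.16 on the strength profile is recovered as
k = 0.147 (slightly attenuated by thresholding and edge noise) with
p ≈ 7·10⁻⁵; the metrics without a planted tilt stay near zero. The full
report (`hubdisrupt run demo --out report`) writes every results table as
CSV plus `summary.json`; on this cohort all four planted affected regions
(L-lateraloccipital, L-pericalcarine, R-lingual, R-paracentral) appear among
the FDR-significant local comparisons, and the best local discriminators in
the ROC table are the affected regions' metrics (e.g. strength of R-lingual,
AUC = 1.0 on this noise level).

The same analyses are available as library calls:

```python
from hubdisrupt import (SimulationConfig, simulate_cohort,
                        AnalysisConfig, run_pipeline)

conns, cohort = simulate_cohort(SimulationConfig(seed=1))
report = run_pipeline(conns, cohort, AnalysisConfig(sparsity=0.10, alpha=0.05))
print(report.disruption_group)        # k, k0, p per metric
print(report.roc_local.head(10))      # local AUCs, ordered high to low
```

Real data enter through `load_dataset(directory)` /
`read_connectome(matrix, labels)`: dense TSV/CSV or MatrixMarket matrices,
a labels file, and a cohort CSV with columns
`subject_id, group, age, sex[, VFI, RNFL, GCL, ...]`.

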