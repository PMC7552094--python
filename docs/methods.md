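# Methods

## Data model

A subject connectome is an N×N symmetric non-negative weight matrix with
zero diagonal over a fixed, ordered parcellation (default N = 84, Desikan
cortical + subcortical labels). Weights are treated as given connectivity
units (e.g. SIFT-filtered streamline counts); no normalization is applied on
input. Row order always equals label-file order; a size/label mismatch is an
error, never silently reindexed. Input asymmetry up to a relative 1e-6 is
repaired as (W + Wᵀ)/2 (tractography matrices are symmetric by construction,
so anything larger indicates file corruption and is rejected); a nonzero
diagonal is zeroed with a logged warning.

## Thresholding

Proportional (sparsity) thresholding keeps the K = ⌊s·N(N−1)/2⌋
largest-weight upper-triangle edges (default s = 0.10 → K = 348 at N = 84)
and zeroes the rest, mirroring to the lower triangle. Floor is used so the
stated sparsity is an upper bound on density. Ties at the K-th weight are
broken by ascending (row, col) index — streamline-count ties are common and
a deterministic rule keeps reruns identical. Weights are *not* binarized:
strength is meaningless on binarized graphs. If fewer than K nonzero edges
exist they are all kept and a warning is logged.

## Graph metrics

All metrics follow the Brain Connectivity Toolbox's weighted-undirected
conventions, written from first principles here:

- **strength**: sᵢ = Σⱼ wᵢⱼ.
- **clustering (Onnela)**: with ŵ = w / max(w) per subject,
  Cᵢ = Σ_{j,h}(ŵᵢⱼ ŵᵢₕ ŵⱼₕ)^{1/3} / (kᵢ(kᵢ−1)), kᵢ = number of nonzero
  neighbors, Cᵢ = 0 for kᵢ < 2. Per-subject max-normalization is the
  toolbox convention; normalizing across subjects would leak group
  information into a within-subject quantity.
- **transitivity**: Σᵢ Σ_{j,h}(ŵᵢⱼ ŵᵢₕ ŵⱼₕ)^{1/3} / Σᵢ kᵢ(kᵢ−1), 0 when the
  denominator vanishes.
- **betweenness**: Brandes accumulation over Dijkstra shortest paths on edge
  lengths 1/w; unnormalized; each unordered source–target pair counts once
  (accumulations from both endpoints are halved); equal-length path ties get
  fractional allocation; disconnected pairs contribute nothing. Exact
  floating-point equality identifies ties, matching the reference
  implementations; random weights make accidental near-ties a measure-zero
  concern and unit-weight ties compare exactly.
- **local efficiency**: for node i with neighbors G_i (kᵢ ≥ 2),
  E_{loc,i} = Σ_{j≠h∈G_i}(ŵᵢⱼ ŵᵢₕ / d_{jh}(G_i))^{1/3} / (kᵢ(kᵢ−1)), where
  d_{jh}(G_i) is the shortest path on lengths 1/ŵ restricted to G_i;
  disconnected neighbor pairs contribute 0.
- **global efficiency**: mean of 1/d over ordered pairs on lengths 1/w,
  with 1/∞ = 0 for disconnected pairs.
- Global summaries: global strength and global clustering are the means of
  the nodal values (the sum convention would only rescale group contrasts,
  not their p-values).

Shortest paths use scipy's sparse-graph Dijkstra where no path counting is
needed; Brandes is implemented directly because path counts are required.

## Disruption index

For metric profile LM over N regions, with control-mean profile
x = (1/C)Σ_{j∈C} LM_j:

- subject-wise: OLS of y = LM_S − x on x over the N regions → slope k_S,
  intercept, residuals;
- group-wise: OLS of (patient-mean profile − x) on x → slope k, with a
  two-sided t-test on the slope (N − 2 df) for k ≠ 0. The t-test is the
  standard inference for an OLS slope; nothing more exotic is warranted by
  the sample sizes involved.

Control subjects' own indices are computed against the full control mean
(the subtrahend in the defining regression is the complete control mean for
every subject); a leave-one-out variant is available as a flag. A constant
control profile makes the slope undefined and raises an error rather than
returning 0 — silent zeros would mask degenerate inputs.

Because the OLS slope is linear in the response, the group-wise k computed
from the mean patient profile is identically the mean of per-patient
subject-wise slopes whenever all regressions share the same control-mean
regressor; the test suite asserts this identity.

### Known limitation: finite-control-sample bias

The control-mean profile is estimated from C subjects and therefore carries
noise that enters *both* regression axes (positively in x, negatively in y).
This biases the index negative under the null by ≈ −σ_c²/(Var(m)+σ_c²)
(regression to the mean) and makes the nominal 5% slope test slightly
anti-conservative: at the default generator settings (C = 15, metric-level
noise sd 0.5 on a profile spread of ~2.6) the measured null rejection rate
is ≈ 6.4%. The calibration test in the suite therefore evaluates the slope
test under the regression model proper (reference profile fixed,
`control_noise_sd = 0` in `simulate_disruption_profiles`), where the 5%
level is exact (measured 5.18% over 5000 replicates); the finite-C artifact
is an inherent property of the index on real data and should be kept in
mind when interpreting small |k|.

## Hub analysis

A region is a hub for a subject and metric when its value strictly exceeds
1.5× the subject's whole-brain mean of that metric. Determining hubs per
subject (rather than from group-average profiles) is what makes a
presence/absence group comparison well-posed. Per region, the 2×2 table of
group × hub status is tested with a two-sided Fisher exact test computed by
hypergeometric enumeration in exact rational arithmetic (ties in table
probability need no floating-point fuzz). Raw p-values are reported
alongside BH-FDR-adjusted ones (across regions, within metric), since
exploratory hub reports often quote uncorrected values.

## Group statistics

- **Mann–Whitney U** with midranks for ties; reported U is min(U_x, U_y).
  Exact enumeration of all C(n+m, n) group assignments when the smaller
  group has < 8 observations (and the enumeration is affordable); otherwise
  the tie-corrected normal approximation with continuity correction. The
  two-sided exact p counts assignments whose min-U is at most the observed.
- **Effect size**: 100·(median_P − median_C)/|median_C|; undefined (error)
  at zero control median.
- **FDR**: Benjamini–Hochberg step-up, adjusted p_(i) = min_{j≥i} m·p_(j)/j
  capped at 1, rejection when adjusted p < α. Families: across regions
  within each local metric; global metrics as one family; disruption
  indices as one family; per clinical variable for associations.
- **Clinical associations**: OLS of metric on (clinical, age, sex-indicator)
  with listwise deletion (≥ 5 complete cases required); Cohen's
  f² = (R²_full − R²_cov)/(1 − R²_full) against the covariates-only model;
  constant covariate columns (e.g. single-sex subsets) are dropped with a
  warning; constant responses are rejected. Fitting uses statsmodels.
- **ROC**: a single-predictor logistic regression is fitted by IRLS on a
  standardized predictor with capped iterations, so perfectly separated
  data converge to a finite large-slope solution instead of diverging. The
  ROC is swept on the raw-predictor axis with patients as the positive class
  ("predict patient when x ≥ t"): the fitted probability is a monotone
  transform of x, so this is the same curve whenever the fitted slope is
  positive, it stays well-defined at zero slope, and a predictor that ranks
  patients *below* controls honestly shows AUC < 0.5 rather than being
  silently flipped. Trapezoid AUC is asserted at runtime against the
  tie-corrected rank (concordance) AUC. Youden's J = max(sens + spec − 1)
  picks the operating threshold, ties broken toward higher sensitivity;
  sensitivity, specificity, PPV, NPV and accuracy come from the confusion
  counts at that threshold.

## Synthetic cohort generator

The generator emulates the statistical structure of a two-group connectome
study; its defaults are the study conditions the pipeline is designed for.

- **Base connectome**: N regions placed uniformly in the unit cube; an edge
  between i and j appears with probability exp(−d_ij/0.6) and carries a
  log-normal weight (log-mean 3.0, log-sd 0.9) attenuated by
  exp(−d_ij/1.2), mimicking the short-range bias of streamline counts.
  The base is regenerated (bounded retries) until the 10%-sparsity graph is
  connected.
- **Group effect**: patient edges incident to the affected regions (default:
  L-lateraloccipital, L-pericalcarine, R-lingual, R-paracentral — occipital
  and paracentral targets) are multiplied by 1.3, matching ~30% effect
  sizes. A multiplicative (not additive) effect makes clustering and
  efficiency respond in the patient > control direction.
- **Planted disruption slope**: after amplification, a symmetric region-wise
  rescaling (iterative proportional fitting on row sums) moves the expected
  patient strength profile to m_amp + (s − s_amp)·m, where s_amp is the
  slope the amplification alone induced. This sets the expected OLS
  disruption slope on strength exactly to s (default 0.16) while
  *preserving* the amplification-driven deviations from the fitted line —
  rescaling straight to (1+s)·m would cancel the local group effect.
  Other metrics inherit correlated reorganization from the same mechanism
  rather than being planted independently.
- **Noise**: per-subject, per-edge multiplicative log-normal noise with unit
  mean and coefficient of variation 0.2, symmetric. With amplification 1 and
  slope 0 both groups are exactly exchangeable (null construction).
- **Clinical scores**: age uniform on 50–76 years; sex Bernoulli(½); RNFL
  (µm) = 85 − 8·z + 6·ε where z is the cohort-standardized strength of the
  first affected region (planting a negative metric–RNFL association of
  8 µm per SD); VFI (%) and GCL (µm) are correlated noisy transforms of
  RNFL; IOP is higher in patients. Missingness is not generated by default.
- `simulate_disruption_profiles` generates metric-level profiles directly
  (uniform [1, 10] control profile, additive homoscedastic noise, patients
  at (1+s)× the profile) for slope-recovery and calibration studies where
  graph construction would only add confounded attenuation.

What the generator does **not** emulate: tractography error modes
(false-positive bundles, gyral bias), distance-dependent noise, site or
head-motion effects, realistic between-subject global scaling, or lesion
anatomy. Passing tests demonstrate the statistical machinery is correct
under the assumed generative structure, not that the biological findings
would replicate.

Edge-level noise makes regional strengths cross-correlated (regions share
edges) and heteroscedastic; combined with the finite-control bias above,
the group-wise slope test on full synthetic graphs rejects a null at ≈ 22%
rather than 5%. The pipeline's null check therefore asserts the absence of
*corrected* significance and a near-nominal raw false-positive fraction,
not exact calibration of the slope test at the graph level.

## Pipeline sizes and determinism

The default end-to-end analysis (38 subjects × 84 regions) runs in a few
seconds; the test suite uses cohorts of 11–38 subjects, oracle graphs of
N ≤ 12, 200 replicates for slope recovery and 500 for calibration. All
randomness flows from explicit seeds (`numpy.random.default_rng`); reports
and datasets regenerated with the same seed are byte-identical, and the
report metadata records a SHA-256 over the input matrices.
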