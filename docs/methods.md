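# Methods

This note documents the models, defaults and design choices behind
`methylmark`, and what the synthetic-data tests do and do not establish.

## Synthetic data model

Beta values are assembled in the logit domain and mapped back through the
inverse logit, which keeps every value inside (0, 1) and makes the
logit-scale batch adjustment exactly invertible for recovery tests. Per
probe, a trimodal baseline (unmethylated / intermediate / methylated, logit
means −2.2 / 0 / 2.2) mimics the bimodal-with-shoulder shape of real arrays.

* **Cell structure.** 120 type-I "discriminating" probes carry one cell type
  shifted ±2.5 logits; each sample mixes the six cell-type profiles in beta
  space with Dirichlet weights. The default concentration
  (1.5, 2.4, 4.5, 1.5, 2.1, 18.0) over (B, CD8T, CD4T, NK, Mono, Gran) gives
  a granulocyte-dominated whole-blood composition with realistic
  person-to-person spread. The same profiles double as the deconvolution
  reference fixture, so no external reference download is needed; a real
  450K reference in the same TSV layout is a drop-in replacement.
* **Planted effects.** Planted probes are placed symmetrically around β = 0.5
  (case 0.5 + Δ/2, control 0.5 − Δ/2, Δ = 0.10 by default). Symmetric
  logit-domain noise then shrinks both group means toward 0.5 by the same
  amount, so the expected beta difference stays within ±0.01 of Δ — the
  property the recovery tests assert at n = 200 + 200.
* **Probe chemistry.** A configurable 72% of probes are type II; their logit
  values are multiplied by 0.8, compressing the dynamic range toward 0.5.
  This is the distortion BMIQ is asked to undo, and the KS-distance test
  checks it actually shrinks per sample.
* **Batch and noise.** Each batch (samples assigned round-robin within group,
  so group and batch are never confounded) gets a scalar logit shift
  ~N(0, 0.2) and a noise-scale multiplier exp(N(0, 0.1)); probe-level noise
  is N(0, 0.25) on the logit scale (≈ 0.06 in beta units mid-range).
  Detection failures (p drawn above 0.01) and bead failures (count < 3)
  occur at rates 5·10⁻⁴ and 10⁻³ per entry.
* **Clinical scores.** Truncated normals at the case/control means
  ADOS 7.0 / 1.5, ASSQ-R 28.6 / 6.1, IQ 110 / 112 (IQ truncated at 80,
  matching a high-functioning cohort). Only the group separation matters
  downstream; the scores are otherwise independent of methylation, so
  marker-vs-severity correlations are null by construction.

What passing tests show: every algorithmic stage recovers what was planted
at the configured sizes. What they do not show: robustness to features real
cohorts have and the generator does not — probe-specific variance structure,
correlated probes in CpG islands, cell-type × disease interactions,
non-Gaussian batch artifacts, genotype-driven outliers.

## Preprocessing

* **QC filter order** is detection → beads → sex chromosomes → SNP →
  cross-reactive; each removed probe is attributed to the first rule that
  fires, so rule counts sum exactly to the number removed. The bead rule
  removes a probe only when the low-bead fraction strictly exceeds 5%; the
  detection rule fires on a single failing sample.
* **Beta mixture EM** fits three beta components with a method-of-moments
  M-step (weighted mean/variance matching), which is stable for values near
  the boundaries; convergence is declared when the log-likelihood gain drops
  below `tol` (default 10⁻⁴, max 100 iterations). Initialization splits the
  data at the fixed state boundaries 0.25 / 0.75 rather than at empirical
  quantiles: quantile seeding forces initial weights of 1/3 each, which EM
  cannot escape when one state dominates, whereas fixed boundaries let a
  concentrated sample put essentially all weight on its single state.
  Near-empty strata start from vague defaults with weight 10⁻³. Components
  are reported in increasing-mean order, ties broken by weight.
* **BMIQ** maps the type-II U stratum through the type-II-U CDF and the
  type-I-U quantile function (lower tail), the M stratum through the upper
  tails, and the H stratum linearly between the transformed U/M boundaries.
  A final cumulative-maximum pass over the rank-ordered values enforces the
  monotonicity invariant exactly, including across stratum boundaries.
* **Batch adjustment** standardizes probes on logit(β) with the group effect
  retained in the design, shrinks per-batch location/scale toward
  moment-matched normal / inverse-gamma priors, and solves the posterior by
  the standard fixed-point iteration (tolerance 10⁻⁴). Batch variables are
  adjusted sequentially in the order given (default sex, then array/batch):
  the underlying study text does not pin down joint vs sequential handling,
  and sequential is reproducible and testable. Guards: a batch level with a
  single sample and batch⊻group confounding are hard errors.

## Cell deconvolution

Nonnegative least squares per sample (active-set NNLS), then renormalization
to the simplex. The raw residual norm is kept on the output so the
renormalization hides nothing; a reference condition number above 10⁶ is
recorded as a warning. Requiring ≥50% reference-probe overlap guards against
silently projecting onto a mismatched panel.

## DMP statistics

Modelling is on beta values directly (not M-values), so the reported effect
size is the raw case−control beta difference the screening rule (FDR ≤ 0.1,
|Δβ| ≥ 0.1) refers to; the group coefficient from the covariate-adjusted fit
is carried separately. The default screening design has no covariates; an
adjusted design (age, sex, cell proportions, …) is available through
`DesignSpec`. The moderation prior (d₀, s₀²) is moment-matched on log s²
(digamma/trigamma inversion); d₀ = ∞ (all variances equal) takes the pure
pooling branch. Forcing d₀ = 0 or ∞ reproduces the ordinary-t and pooled-t
limits, which the tests assert numerically.

One caveat is deliberate: with a true effect exactly at the |Δβ| ≥ 0.1
threshold, the observed delta falls below threshold about half the time by
symmetry, so threshold-recall of planted 0.10 effects hovers near 0.5. The
suite therefore checks recall against the FDR criterion plus enrichment of
the joint selection, which is the scientifically meaningful property.

## CALF

Features are z-scored on the training samples before signed summation —
±1 weights are only meaningful on a common scale; this is the largest free
choice in the module and is recorded here prominently. The metric is
|Pearson r| with the sign folded into the weight (AUC available as an
alternative); acceptance requires strict improvement, ties go to the lowest
feature index and +1 before −1, and selection stops at 10 features by
default. The permutation p-value is max(b, 1)/N (floor 1/N = 5.0·10⁻⁴ at
N = 2000); the (b+1)/(N+1) estimator is available behind a flag. Stability
selection draws ⌈0.8·n⌉ per class without replacement — class-stratified, so
group imbalance cannot drift across trials — and flags features selected in
≥750 of 2000 trials. For the Pearson metric all permutations advance through
the greedy steps simultaneously via closed-form covariance updates; the test
suite asserts this matches the scalar per-permutation procedure to
floating-point rounding.

## Random forest

scikit-learn's `RandomForestClassifier` supplies the forest (500 trees,
bootstrap of size n per tree, Gini splitting, no class weighting). MDG is the
per-tree sum of node-proportion-weighted impurity decreases per feature,
averaged over trees; per-tree conservation (feature decreases summing to the
tree's total impurity reduction) is asserted in the tests. mtry is tuned by
repeated stratified 10-fold CV (3 repeats by default — the repeat count is
the package's choice) over ⌊√p⌋ ± 2 clipped to [1, p], ties to the smallest
value; when the smaller class has fewer members than the fold count, the
fold count degrades to that class size.

## Evaluation

AUC is the midrank Mann–Whitney statistic. Covariate adjustment fits
label ~ marker + age + sex by IRLS (tolerance 10⁻⁸, 100 iterations); on
perfect separation the coefficients are not identified, so the summary falls
back to the unadjusted marker AUC with a note — on separable data the two
agree anyway. Constant covariates are dropped (absorbed by the intercept).
The CI is a percentile interval over class-stratified bootstrap resamples
(2000 by default); stratification guarantees both classes in every
replicate. The operating point maximizes Youden's J over score midpoints
with ties resolved toward higher specificity — the underlying study never
states its operating-point criterion, so the choice is logged in every
report.

## Pipeline and reproducibility

Stage order: QC → BMIQ → batch → deconvolution → DMPs → forest + CALF →
consensus → ROC. Each stage's seed is CRC32(stage name) XOR the global seed,
reduced mod 2³¹, so stages are individually reproducible without seed
collisions. All report files use fixed numeric formats and carry no
timestamps; two runs with the same configuration are byte-identical, which
the tests assert file-by-file.

## Problem sizes in the test suite

The suite exercises the study-scale settings (2000 permutations, 2000
stability trials, 500 trees, n_boot 2000) where the criterion under test
needs them, and smaller but structurally identical instances elsewhere:
the end-to-end determinism runs use 1200 probes, 25+25 samples, 500
permutations/trials and 200 trees; the permutation-null calibration uses
2000 replicates of an 8-feature instance at 1000 permutations each (the
exact null rejection rate at 0.05 is 51/1001 ≈ 0.051, and 2000 replicates
give the Monte-Carlo resolution the ±0.01 band requires). These sizes are
the package's own defaults for its checks.

## Known limitations

* The ComBat-style adjustment implements the parametric prior only.
* BMIQ's H-stratum dilation is a single linear map between the transformed
  boundaries (no per-probe spline refinement).
* CALF's regression (continuous-outcome) mode and weight magnitudes beyond
  ±1 are out of scope, as are DMR (region-level) analysis, reference-free
  deconvolution, and analytic (DeLong) AUC intervals.
* The synthetic generator's realism limits are listed above; nothing here
  validates performance on real cohort data.
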