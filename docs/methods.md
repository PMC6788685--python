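# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the places where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design

The pipeline implements a two-cohort biomarker design for aptamer-panel
plasma proteomics. A single-site discovery cohort (96 PD, 45
neurologically normal controls; 1,129-plex panel) nominates candidate
proteins; a multisite replication cohort (215 PD, 102 NC, two clinical
sites, five assay plates; 1,305-plex panel) confirms them; auxiliary
cohorts probe disease specificity (59 ALS), medication state (10 PD
sampled on and off dopaminergic medication) and sample handling
(matched reference-pool aliquots). Longitudinal cognitive scores in the
PD groups support progression models. All analysis operates on log10
relative-fluorescence units (RFU).

## QC and normalization

* **Hybridization normalization**: per sample,
  `factor_i = median_c(reference_c / observed_ic)` over spiked-in
  control aptamers; all of sample *i* is multiplied by `factor_i`.
  When no external reference is given, each control's across-sample
  median serves as its reference — a self-contained default replacing
  vendor calibrator files.
* **Median normalization**: with `r_j` the across-sample median of
  protein *j*, `factor_i = median_j(r_j / x_ij)`. The post-condition
  `median_j(r_j / x'_ij) = 1` (with respect to the *original* `r_j`)
  holds exactly and is tested exactly. Re-applying the operation
  recomputes medians from normalized data, so second-pass factors are
  only approximately 1 (a few percent on realistic matrices); the
  idempotence test uses a 5 % band.
* **Scale-factor gate**: samples pass iff `0.4 <= factor <= 2.5`.
  The published range carries no boundary semantics; inclusive-pass
  was chosen and is pinned by tests.
* **Triplicate CV filter**: CV = sample standard deviation (ddof = 1)
  divided by mean, on raw RFU, one per reference-pool triplicate; a
  protein is excluded iff *any* triplicate CV strictly exceeds 0.2.
  The (n−1) denominator is the conventional choice for triplicates and
  makes the 0.2 boundary unambiguous.
* **LOD filter**: excluded iff strictly more than 25 % of a protein's
  measurements fall outside its [LLOD, ULOD] annotations. Proteins
  without annotations pass with a logged warning — panels whose vendor
  published no limits simply skip the filter (the replication panel's
  situation).
* CV and LOD filters read disjoint evidence (reference-pool runs vs
  cohort measurements), so the combined exclusion set is
  order-independent; `run_qc` applies both after normalization.

## Discovery model

Per protein: ordinary least squares of log10 level on an intercept,
group (PD = 1, NC = 0), age (years), sex (female = 1) and
levodopa-equivalent daily dose (LEDD, mg/day; 0 for untreated and
control participants). Covariates enter unscaled so coefficients stay
interpretable (log10-RFU per unit). The group t statistic uses the
residual-df t reference distribution. Because the design matrix is
shared across the panel, one factorization serves every protein
(hand-vectorized multi-response OLS, cross-checked against statsmodels
per-protein fits). Candidates: group-effect p < 0.005, strictly;
Benjamini–Hochberg q over the full tested family. LEDD = 0 for
controls makes LEDD strongly collinear with group — a property of the
real design, retained deliberately; it widens the group coefficient's
standard error.

Candidate clustering: per-protein z-scores, agglomerative clustering
with euclidean distance and average linkage on both axes; a
zero-variance protein cannot be scaled and is rejected. Dendrograms
export to Newick.

## Stability selection

Candidates are ranked by how often the LASSO
(½‖y − Xβ‖² + λ‖β‖₁, y = centered group code, X = columns standardized
within the subsample) assigns them a nonzero coefficient across
jackknifed iterations that drop round(10 % · n) samples and
round(30 % · p) features. Frequency = selected / in-bag iterations
(out-of-bag features cannot be selected, so the in-bag denominator is
the honest one; this changes absolute frequencies, not expected
ranks). Rank ties break by mean |coefficient| across selected
iterations, then protein id, so the top-10 is deterministic.

Penalty policy: a 20-point geometric grid from the per-subsample
λ_max = max|Xᵀy| down to **0.3·λ_max**, selection = nonzero anywhere on
the grid (selection over a penalty region, not at a single tuned
penalty). The floor matters: measured on global-null panels, extending
the grid to 0.1·λ_max lets most in-bag features enter somewhere along
the path, driving null selection frequencies toward 1 and flattening
the ranking; at 0.3·λ_max the per-iteration active set stays sparse
while planted effects of 0.15 log10 units retain frequencies near 1.0.

One caveat about null behaviour that any user of stability selection
should know: subsampling re-samples a *fixed* dataset, so the one
noise feature with the largest chance sample-correlation to the labels
is itself stably re-selected; the null signature is a low *central*
frequency across the panel, not a low maximum.

The solver is coordinate descent on the Gram representation
(G = XᵀX, c = Xᵀy) with warm starts along the grid, jit-compiled; it is
validated against scikit-learn's `lasso_path` and against the
closed-form soft-threshold solution on orthonormal designs. Default
10,000 iterations: frequencies are binomial proportions, so their
Monte-Carlo error is already < 0.005 at 10⁴ draws; the original
analysis's 10⁵ changes ranks negligibly and is available by
configuration.

A logistic-LASSO variant was considered and deliberately not made the
default: the linear coding (PD = 1 / NC = 0, centered) matches the
variable-selection-on-class-label usage and keeps λ_max closed-form.

## Replication and specificity

The replication estimator is the discovery estimator with site and
batch as reference-coded categorical covariates (five plates → four
indicators, plate 1 reference) and without LEDD — mirroring the
prespecified deviation of the original analysis plan (LEDD was not
uniformly available in the replication cohort). BH correction runs
over the prespecified top-k family only, not the whole panel.
Replication requires q < 0.05 in both cohorts *and* sign concordance;
the check is symmetric in its inputs. Proteins absent from the
replication panel are reported untestable, not failed.

Specificity: a three-level disease factor (NC reference) with age, sex
and site; the PD and ALS coefficients are extracted per protein and
pooled into a single BH family. The never-treated comparison is a
two-sided Mann–Whitney test: exact for combined n ≤ 20 without ties,
normal approximation with tie correction otherwise.

## Robustness stage

Paired medication-state tests run per protein on log10 levels across
matched on/off draws. The paired t test reports p = 1 with a
`degenerate` flag when all differences are zero (an unaffected protein
is unremarkable, not missing). The permutation test uses |mean
difference| as statistic — the natural two-sided choice; the exact path
enumerates all 2ⁿ sign flips for n ≤ 12 (1,024 flips at the n = 10 of
the medication substudy), so exact p-values are multiples of 2⁻ⁿ and
≥ 2⁻ⁿ; the Monte-Carlo path uses the add-one convention
p = (1 + hits)/(B + 1), which guarantees validity. Handling percent
change is computed on raw RFU (not log10), flagged at |change| > 30 %.

## Progression models

* **Mixed model**: score ~ age + sex + disease duration + baseline
  score + time + time×protein, participant random intercept, REML.
  The time main effect accompanies the interaction (an interaction
  without its marginal term is not interpretable). Because the
  baseline score is a covariate, the baseline visit is excluded from
  the response — keeping it would place the same measurement error on
  both sides of the model and (as the coverage study in the acceptance
  suite shows) degrade confidence-interval calibration. Random slopes
  are available behind the fixed-effects fallback path but the default
  structure is intercept-only, the minimal reading of "participant as
  a random effect". A singular random-effects fit falls back to OLS
  with a logged warning.
* **Cognitive staging**: MoCA 26–30 normal, 21–25 MCI, ≤ 20 dementia.
  DRS-based states come from consensus diagnosis and are inputs, never
  derived.
* **Events**: first worsening transition (normal→MCI, normal→dementia,
  MCI→dementia) at that visit's time; censoring at the last visit.
  Excluded: dementia at baseline, and any normal state after a
  baseline MCI (diagnostic instability).
* **Tertiles**: cut at the 1/3 and 2/3 linear-interpolation sample
  quantiles of the baseline log10 level; ties go to the lower tertile.
  This convention is pinned because alternative quantile rules shift
  boundary participants.
* **Cox**: lifelines partial likelihood with Efron tie handling;
  covariates age, sex, disease duration (+ education on request). The
  tertile enters categorically with the *highest* tertile as reference
  so the headline hazard ratio reads lowest-vs-highest — the contrast
  matching "elevated risk in the lowest tertile"; a lowest-vs-rest
  indicator contrast is available because the published contrast is
  not fully pinned down. Education sensitivity uses a likelihood-ratio
  comparison of the nested models.

## Synthetic-data generator

The generator is the package's test bed and defines the conditions the
acceptance checks run under. Raw RFU for sample *i*, protein *j*:

    10 ^ ( baseline_j + delta_j·1[PD] + 0.002·(age_i − mean age)
           + 0.02·1[female] + site_shift + batch_shift + noise_ij )

* Baselines uniform on [2.5, 4.5] log10 (typical plasma assay dynamic
  range). Ages truncated-normal(70, 8) on [45, 95]; sex Bernoulli(½);
  both drawn identically for PD and NC so the groups match in
  expectation.
* Planted group effects: ±delta (alternating sign) on a random subset;
  default 20 proteins at 0.1 log10 units — a testability choice, since
  the source study reports no effect sizes on the RFU scale.
* Correlated blocks: noise_ij = noise_sd·(√ρ·f_{i,b(j)} + √(1−ρ)·ε_ij)
  with one latent factor per (sample, block of 10); the within-block
  correlation is exactly ρ (default 0.5), reproducing the colinearity
  that motivates stability selection.
* Site/batch shifts are drawn per (site, protein) and per (batch,
  protein) with SD 0.05 log10 — multiplicative on the raw scale, and
  exactly the structure a per-protein categorical covariate absorbs.
* LOD pressure: a designated fraction of proteins (default 125/1129)
  gets its baseline placed just above the LLOD so ≈ 35 % of its
  measurements fall below — safely past the 25 % exclusion rule; the
  remaining proteins essentially never trip it. QC triplicates are
  log-normal with the population CV set exactly to the target (0.05,
  or 0.5 for the default 36 designated noisy aptamers).
* Longitudinal scores: intercept_i + (base_slope + γ·x_i)·t + ε with a
  participant random intercept (SD 5), residual SD 2, baseline 137
  (the observed mean of the discovery cohort's dementia rating scale),
  base slope −1/year; x_i is the participant's baseline log10 level.
  Scores are not clipped to the scale range — clipping would break the
  linear model the LMM stage assumes and the defaults keep
  trajectories well inside it.
* Conversion times: exponential with log-hazard = cox_loghr·1[lowest
  tertile] (+ optional covariate terms), baseline hazard 0.13/year
  (≈ the observed 38 events / 86 participants / 3.5 years),
  administrative censoring at follow-up. Default planted HR: 2.27.
* Reproducibility: one global seed; each generator stage draws from an
  independent child stream (`SeedSequence(seed, spawn_key=(stage,))`
  with fixed per-stage keys), so re-running any stage alone reproduces
  its output bit-identically.

What the generator does **not** emulate: binding kinetics and
plate-geometry artifacts, heavy-tailed or protein-specific noise,
missing visits, informative censoring, and measurement error in
covariates. Passing tests therefore demonstrate that the *estimators
recover what was planted under the assumed model*, not that the model
captures every property of real plasma data.

## Problem sizes and numerics

The acceptance suite runs the stages at the study's own scale: null
calibration on 968-protein cohorts of 141 samples (4 seeds, pooled);
stability recovery as 20 runs × 10,000 iterations on 140-candidate
panels; mixed-model coverage as 200 replicates at 90 participants × 4
visits; Cox recovery at n = 600. The acceptance script reports a
5-run stability recovery rate to keep a full from-scratch rerun around
a minute of compute. The KS uniformity check uses one protein per
correlated block — the independent units — because the KS reference
distribution assumes iid draws and within-block correlation would
invalidate it.

Solver tolerances: LASSO coordinate descent stops at max coefficient
update < 1e-7 (retried with a 20× budget before a logged give-up);
OLS flags designs as rank-deficient via the QR diagonal at machine
precision scaled by dimension, and rejects responses with residual
variance below 1e-12 of the response scale; permutation comparisons
use a 1e-12 slack so sign-symmetric statistics count as ties.

## Known limitations

* The replication BH family is the prespecified top-k only; panel-wide
  replication FDR is not computed.
* No meta-analytic pooling across cohorts; cohorts stay separate by
  design.
* Motor progression is out of scope; only cognitive trajectories are
  modeled.
* The measured cohorts' exact counts (e.g. candidate and retention
  totals) can only be reproduced with the measured data present; the
  package ships none of it.
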