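# Methods

`ctibm` implements an imaging-biomarker (IBM) survival workflow for
contrast-enhanced CT of oesophageal squamous cell carcinoma: feature
extraction from a delineated primary tumour, feature pre-selection,
construction of a LASSO-Cox risk score, risk stratification, individual
survival prediction and decision-curve analysis. This note records the
model choices, conventions and their rationale.

## Feature extraction

Ninety-six features are computed per (volume, mask) pair, in six
families: 24 first-order intensity statistics, 20 geometric descriptors
and 52 texture features (GLCM 20, GLRLM 16, NGTDM 5, GLSZM 11). The
registry (`ctibm.features.registry`) fixes names, families and order and
asserts the census at import time. Thirteen of the names — Range, Q75,
Q975, Sphericity, Major_axis_length, Volume_Density,
Maximum_Probability_GLCM, Sum_of_Square_Variance_GLCM, Coarseness_NGTDM,
Contrast_NGTDM, Busyness_NGTDM, Small_Zone_Emphasis_GLSZM,
Zone_percentage_GLSZM — are pinned by the published scoring formulas;
the remaining members are the field's canonical definitions for each
family, chosen to fill the stated per-family counts. The registry is
data-driven, so individual members can be swapped without touching the
matrix engines.

Conventions, fixed once for the whole package:

- **Native grid, physical units.** No resampling by default (planning
  CTs come at 1.0×1.0×3.0 or 1.0×1.0×5.0 mm voxels); all geometry uses
  millimetres. An optional isotropic resampler exists for sensitivity
  analyses (`resample_to_isotropic`) and is off everywhere else.
- **Discretisation.** Fixed bin number, N = 32, computed on in-mask
  intensities (`level = 1 + floor(N (v − min)/(max − min))`, maximum
  clipped into bin N). Fixed bin width is available. A constant ROI maps
  to a single level. Intensity statistics use raw values except
  histogram entropy and uniformity, which use the discretised histogram.
- **Texture geometry.** The 13 unique 3D offsets at Chebyshev distance 1,
  with unit direction weights regardless of physical anisotropy — the
  common convention when features are extracted on the native grid; it
  is a documented limitation, not an oversight. GLCM counts are
  symmetrised and, like GLRLM runs, pooled over all 13 directions into
  one matrix *before* features are computed. NGTDM neighbourhoods and
  GLSZM zones are 26-connected and mask-restricted; out-of-mask voxels
  never pair with, extend, neighbour or join anything.
- **Surface area** is exposed-voxel-face area. This is exactly testable
  (cube: 6a²; box closed forms) at the cost of a known positive offset
  versus meshed surfaces on curved shapes; sphericity and its relatives
  inherit that offset consistently.
- **Axis lengths** are 4·sqrt(eigenvalues) of the physical-coordinate
  covariance of in-mask voxel centres, in descending order.
- **Degenerate inputs.** Single-voxel ROIs return 0 for undefined
  dispersion/shape moments rather than failing the patient; a flat grey
  field caps NGTDM coarseness at 10⁶; an ROI in which no voxel has a
  neighbour returns all-zero NGTDM features; GLCM correlation of a flat
  field is defined as 1.

Every texture feature is verified against brute-force enumeration
oracles (explicit pair/run/neighbourhood/zone loops, written
independently in the test suite) on ≥50 random ROIs of ≤6³ voxels at
Ng ≤ 4, to 1e-10 relative tolerance.

## Pre-selection

Three rules, applied to the training cohort only:

1. Univariable Cox screen per standardised feature; keep Wald p < 0.25.
   Constant features are dropped with p set to 1 and flagged.
2. Correlation pruning: among kept features, while any pair has
   |Pearson r| ≥ 0.8, delete the feature with the larger univariable p
   (ties break by registry order); the deletion order is logged.
3. Variance inflation factors (1/(1−R²) from OLS of each retained
   feature on the others) as a collinearity diagnostic; exact
   collinearity reports +inf.

Features are standardised (training mean/SD) before every model fit so
the L1 penalty treats features on different native scales comparably.

## The IBM score

The score is the log-partial hazard of an L1-penalised Cox model plus a
constant. The penalty path (100 log-spaced values spanning four decades
below the smallest all-zero penalty) is fit with coordinate descent
(scikit-survival's Coxnet); the penalty is chosen at the minimum of
10-fold cross-validated partial-likelihood deviance, with folds
stratified by event status and a seeded, recorded assignment. Held-out
deviance uses the package's own Breslow partial log-likelihood. The
constant is the smallest multiple of 0.1 making every training score
strictly positive (a training minimum linear predictor of −2.43 yields
+2.5). The resulting `ScoreFormula` embeds its scaling statistics, so it
is self-contained and JSON round-trips bit-exactly.

Two published formulas are frozen verbatim: overall survival (11 terms,
constant +2.5) and progression-free survival (8 terms, constant −1.4).
Their coefficients are interpreted as acting on *standardised* feature
values: against raw CT-scale inputs (an upper intensity percentile of
several hundred HU times a coefficient of −3.231) the printed constants
could not keep scores positive. This is an interpretive assumption, not
a claim about the original fitting procedure; raw-scale application is
possible by constructing a formula without a scaling spec.

When cross-validation prefers the fully shrunk empty model — the
expected outcome on data with no prognostic signal — `relax_to_nonzero`
can re-select the best penalty with a nonempty active set so the
pipeline still emits a (prognostically useless) score; it warns when it
triggers and never activates in the presence of signal.

## Evaluation

- **Concordance**: Harrell's C over usable pairs, score ties counting ½;
  95% CIs by seeded percentile bootstrap (default 1000 resamples).
- **Time-dependent ROC** at horizon τ: cumulative cases (event ≤ τ),
  dynamic controls (time > τ), inverse-probability-of-censoring weights
  from the Kaplan-Meier estimate of the censoring distribution; AUC by
  trapezoid along the threshold-ordered curve. With no censoring before
  τ this collapses to the empirical ROC of event-by-τ labels.
- **Cutoff**: the threshold maximising Youden's J, ties resolved toward
  higher specificity, reported as the midpoint between adjacent observed
  scores. Cutoffs are learned on the training cohort and applied
  unchanged to validation.
- **KM / log-rank / Cox** go through lifelines (Greenwood variance,
  Breslow baseline). Backward likelihood-ratio elimination removes, one
  at a time, the covariate whose removal has the largest LR p above
  0.10; both the full and final tables are reported because published
  stepwise tables are often ambiguous about which stage they show.
- **Balance tests**: pooled-variance t-test for continuous variables,
  Pearson chi-squared without continuity correction for categorical
  ones (this reproduces the published sex-split p of 0.841 exactly).

## Nomogram and decision curves

The nomogram is a univariable Cox model on the score with a Breslow
baseline cumulative hazard; S(t|x) = exp(−H₀(t)·e^{β(x−x̄)}). Points are
an affine 0–100 rescaling of the observed training score range. Median
survival is reported only within follow-up ("not reached" otherwise);
out-of-range scores predict with a warning.

Decision curves use the survival-weighted formulation: at threshold
probability p_t, the "positive" group is everyone whose predicted risk
at τ reaches p_t, its event probability is estimated by Kaplan-Meier
*within* the group (so censoring is handled), and net benefit is
(n₊/n)[risk₊ − (1−risk₊)·p_t/(1−p_t)]. Treat-all uses the whole cohort;
treat-none is identically zero. An empty positive group contributes
zero net benefit. The binary-count variant would be biased by censoring
at 5-year horizons, which is why the weighted form is the default and
only implementation.

## Synthetic cohorts

The generator supplies the study conditions for every test:

- **Tumours** are ellipsoids discretised at voxel centres on an
  anisotropic grid (default 1×1×3 mm), semi-axes sampled uniformly with
  a 10–22 mm major axis. In-mask intensity is a mean (60 ± 8 HU across
  patients) plus a stationary Gaussian random field: white noise
  smoothed with a Gaussian kernel of width `smoothing_sigma_mm`
  (0.5–3 mm across patients) and rescaled to a fixed marginal SD of
  12 HU — so the correlation length varies while the histogram width
  does not, giving the texture families a real, isolated signal. NGTDM
  coarseness increases monotonically in the smoothing width (verified
  over a 5-point sweep). Outside the mask every voxel is a constant
  −100; a test asserts extraction is background-invariant.
- **Survival** is exponential with hazard 0.02/month times
  exp(linear predictor), so proportional hazards holds exactly and Cox
  recovery is a clean test. Censoring is the minimum of an 84-month
  administrative horizon and a uniform draw on (0, 250] months; the
  event fraction is monotone in the censoring parameter. The linear
  predictor is a configured combination of standardised generative
  parameters (log major axis, smoothing width), so specific features
  are informative *by construction*.
- **Tabular cohorts** (`generate_feature_cohort`) plant a Cox effect
  (default: 3 informative columns, coefficient 0.7 each, pairwise
  equicorrelation 0.2 among 30 columns) for exercising the model stack
  without images.

What passing tests do and do not show: the phantoms have exact
proportional hazards, stationary texture, perfect masks and a single
lesion per patient. Real planning CTs violate all four (contrast timing,
delineation variability, reconstruction kernels, non-PH hazards), so
recovery here validates the *machinery*, not clinical performance.

## Problem sizes and determinism

Tests run the image-based pipeline at n = 154 patients (99/55 split,
the study's own design) for planted-effect recovery and n = 300 over
five seeds for the null check; signature recovery experiments use
tabular cohorts at n = 300 with 20 (selection) and 5 (validation
concordance) seeds. Every random quantity flows from named integer
seeds (simulation, folds, bootstrap); a re-run with the same config
produces a byte-identical report. The full suite completes in a few
minutes on one CPU.

## Known limitations

- Direction weights ignore anisotropy; features at 3 mm and 5 mm slice
  thickness are not harmonised (neither were the originals).
- Face-counting surface area overestimates meshed surface area on
  curved shapes by a systematic, shape-dependent factor.
- The published formulas cannot be validated numerically against their
  source cohort (the imaging data are unavailable); they are frozen as
  printed and exercised structurally.
- No competing risks, time-varying covariates or PH diagnostics.
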