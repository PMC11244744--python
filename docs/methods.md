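# Methods

## The imbalance model

CSF Aβ42 and amyloid-PET measure biochemically different pools of β-amyloid:
soluble peptide in cerebrospinal fluid and fibrillar plaque load in tissue.
Across the Alzheimer continuum the joint distribution of the two markers
follows a steep, monotonically decreasing, hyperbola-like curve in the
(Centiloid, CSF-Aβ42) plane: soluble Aβ42 collapses early while plaque load
keeps rising.  `abimbalance` models that curve explicitly and converts each
subject's position relative to it into two interpretable quantities:

* the **aggregation score** — the signed orthogonal (total-least-squares
  style) Euclidean distance of the observed point from the curve,
  z-standardized within the fitting cohort.  Positive = more PET burden than
  expected for the observed CSF level (relatively more aggregated Aβ);
  negative = relatively more soluble Aβ.
* the **severity score** — the signed straight-line (chord) distance between
  the subject's projection onto the curve and the cohort's reference point
  (the curve point at the median projected Centiloid), z-standardized within
  the cohort.  Positive = further along the amyloid-accumulation trajectory.

Both standardizations use the sample (n−1) SD, one convention applied
everywhere in the package, so within the fitting cohort each score has mean
0 and SD 1 exactly; new subjects are scored with the frozen moments.

### Curve families

Three three-parameter families are supported, all strictly decreasing over
their working domain:

| key          | form                    | default |
|--------------|-------------------------|---------|
| `rational`   | y = a + b·x/(x − c)     | yes     |
| `reciprocal` | y = a + b/(x − c)       |         |
| `log10`      | y = a + b·log10(x − c)  |         |

`rational` is the default because fitted parameter sets of the magnitude
reported for mass-spectrometry CSF units (a ≈ 3.7·10³ pg/mL, b ≈ −2.9·10³,
c ≈ −0.3 CL) — and equally for z-scored CSF units (a ≈ 0.5, b ≈ −2.2,
c ≈ −0.4) — describe a strictly decreasing curve under this family, with
`a` the CSF level at 0 CL and `a + b` the high-burden asymptote, whereas the
rectangular family is increasing for parameters of those signs.  All
geometry, scoring and fitting are form-generic.

### Fitting

The objective is the **sum of orthogonal Euclidean distances** (an L1
criterion over orthogonal residuals; a sum-of-squares variant is available
via `objective="l2"`).  Distances may be measured in the supplied units
(default) or with axes divided by cohort SDs (`scaling="zscore"`) or custom
factors; the choice is frozen into the fitted model and reused for scoring.

Point projection is a 512-point coarse bracket over the curve domain,
vectorized golden-section refinement to `1e-8` of the domain width, and a
Newton polish of the orthogonality condition
`(t − x)/sx² + f′(t)(f(t) − y)/sy² = 0` — the polish restores full relative
precision for near-on-curve points, where a bracketing tolerance alone
leaves an amplified relative distance error.  Equidistant ties resolve to
the smaller Centiloid.  The curve domain defaults to the data range padded
by 5 CL, clamped a *tiny* (10⁻⁶ of the width) margin away from the family's
pole: the near-pole cliff is a legitimate part of the curve that carries the
projections of low-burden subjects, so a generous margin would silently
truncate it.

The outer optimization is multi-start Nelder-Mead on (a, b, c), rescaled by
the initial guess.  Initialization scans the pole location `c` on a
geometric grid on both admissible sides of the data, solves (a, b) in closed
form per `c` (the families are linear in (a, b) given `c`), and refines the
best scan points by bounded 1-D minimization of the vertical-SSE profile —
the profile minimum is far sharper than a coarse grid resolves.  Twenty
restarts by default: the top profile candidates plus Latin-hypercube
perturbations, each given a short coarse run, then one tight polish of the
best coarse optimum (`maxfev=3000`).  The monotone-decreasing constraint is
a 10⁶-scaled penalty proportional to the violation, so the search can cross
infeasible regions.  The fit is deterministic given `random_state`.

Goodness of fit is a total-variance pseudo-R²:
`1 − Σ dᵢ² / Σ ‖pᵢ − centroid‖²`, computed in the fitting scale.  It equals
1 exactly for a noiseless cohort and is undefined (raised) when all points
coincide.

### Identifiability caveat

When |c| is much smaller than the Centiloid range, the family is effectively
two-parameter over most of the data (`y ≈ (a + b) + bc/x` for `x ≫ |c|`):
the objective has a long curved valley along which (a, b, c) trade off while
the curve barely moves.  Under realistic noise the individual parameters are
then not separately estimable — but every quantity the package actually
delivers (projections, distances, both scores, pseudo-R²) is a function of
the curve, not the parameterization, and is stable across the valley
(round-trip score correlation ≥ 0.999 in the generator tests).  Parameter-
recovery benchmarks therefore use a well-conditioned configuration
(|c| comparable to the data scale); interpret printed (a, b, c) values as a
description of the curve, not as separately meaningful constants.

## Harmonization

* **SUVr → Centiloid**: linear per-tracer maps (`CL = slope·SUVr +
  intercept`), supplied as configuration data — calibration slopes are
  pipeline-specific and the package ships only documented placeholder
  entries.
* **Reference-group z-scoring**: CSF (and cognitive) measures can be pooled
  across kits by standardizing against a cognitively-unimpaired reference
  group selected as: baseline visit, CDR = 0, MMSE > 27 (strict), APOE-ε4
  noncarrier, age ≤ 70 (inclusive), Centiloid < 12 (strict).  Every
  exclusion is counted per criterion in a machine-readable log.
* **ICV normalization**: volumes divided by total intracranial volume
  (dimensionless ratios, ~0.03 for ventricles).
* **Aβ42/40 ratio** for the CSF-dynamics sensitivity re-fit; nonpositive or
  missing Aβ40 propagates as missing with a log entry.

## Synthetic cohorts

The generator draws, per subject: demographic covariates (age 73 ± 7.4 y,
46.7% female, APOE-ε4 copy probabilities 0.55/0.36/0.10, education
16.3 ± 2.6 y); an arc position on the Centiloid axis from a two-component
truncated-normal mixture (weights 0.55/0.45, means 5/60 CL, SDs 8/30 CL)
mimicking the characteristic amyloid-negative/-positive bimodality; and a
raw displacement `dᵢ = noise_sd · Σ βₖ·covᵢₖ + εᵢ` applied along the local
unit normal of the truth curve, so `dᵢ` is *exactly* the quantity the scorer
estimates.  Displacement geometry defaults to standardized plane units (axes
divided by the SDs of the noiseless curve points; `noise_sd = 0.05 ≈ 2%` of
the standardized CSF range) because in raw pg/mL-vs-CL units the same noise
level becomes a ±60 CL horizontal perturbation.  Covariate effect sizes are
configured in noise-SD multiples (defaults: APOE-ε4 homozygote −0.56, female
+0.18, ventricular volume −0.13 — magnitudes typical of published
cross-sectional associations).  CSF tau and Aβ38/40 are generated with
positive couplings to displacement and position; vascular, clinical and
interval columns complete the table.  Longitudinal cognition follows
`z = α + λ_sev·sev + λ_agg·agg + (θ_t + θ_agg·agg + θ_sev·sev + u₁)·t + u₀ + ε`
with correlated normal random intercept/slope (SDs 0.7 / 0.15, r = −0.2,
residual 0.4) and annual visits over 3 years; the default
aggregation-by-time coefficient is +0.14 SD/yr.

What the generator does **not** emulate: assay drift and batch effects,
truncation/floor effects of real immunoassays, informative dropout,
non-normal cognitive floors/ceilings, or any mechanistic CSF
production–clearance dynamics.  Passing tests demonstrate the pipeline's
internal consistency and statistical calibration under the assumed data
model, not the clinical validity of the scores.

## Association battery

Cross-sectional models are OLS on the aggregation score; longitudinal models
are linear mixed models (REML) with correlated per-subject random intercept
and slope, fitted via statsmodels, with Wald normal-approximation p-values
(Satterthwaite/Kenward–Roger degrees of freedom are not available in the
backend and are not approximated by hand).  Standardized betas: continuous
outcome and predictors are z-scored within each model's complete-case
sample; categorical predictors are treatment-coded against fixed references
(male, 0 APOE-ε4 copies, Fazekas 0, with Fazekas 2 and 3 merged) and left
unscaled, so their coefficients read as outcome-SD shifts; time is coded in
years from baseline and never standardized, so slope terms read as SD/yr.
Missing data are handled by listwise deletion per model.

Model families: methodological (CSF–PET interval + ventricular volume, plus
kit/tracer labels when present), demographics (age, sex, education, APOE
copies, concurrent), CSF biomarkers (each of Aβ38/Aβ40/p-tau/t-tau
individually, raw and divided by Aβ40, adjusted for age/sex/APOE), vascular
burden (WMH volume, or Fazekas categories when volumes are absent), and one
mixed model per cognitive test reporting the baseline (aggregation at
time 0) and slope (aggregation × time) terms separately.  Every model is
additionally adjusted for severity and ventricular volume.
Predictor × severity two-way interactions (and the aggregation × severity ×
time three-way with all lower-order terms) are optional variants.
Benjamini–Hochberg FDR is applied within the CSF family and within the
baseline/longitudinal cognition families — the families whose model counts
drive the correction — while methodological/demographic families are
reported unadjusted.  Two-group cohort comparisons are pooled-variance t
tests (computable from printed summary statistics), Wilcoxon rank-sum tests
(R's W convention), and continuity-corrected chi-square tests on 2×2 counts.

## Numerical and testing choices

* All stochastic draws flow from seeded `numpy` generators; identical
  configurations produce byte-identical outputs (run logs carry the seed and
  a config hash, and no timestamps).
* A cohort whose raw-score spread is below 10⁻⁴ of its plane scale is
  treated as lying on the curve (degenerate for standardization): an exactly
  on-curve cohort leaves optimizer-tolerance residuals, never true zeros.
* Out-of-domain points are scored against the nearest domain endpoint,
  flagged, and warned about.
* The test suite's heavier studies use deliberately sized problems —
  100-seed recovery at n = 800, 400 null replicates at n = 200, 100
  mixed-model replicates at n = 650 with four annual visits — chosen to make
  the Monte-Carlo bands informative while keeping the default run practical
  on one CPU.

## Known limitations

* The exact algebraic form used in the original MATLAB implementation is not
  public; the package makes the family explicit and configurable instead.
* Mixed-model p-values use the normal approximation; for small cohorts they
  are mildly anti-conservative relative to Satterthwaite-type corrections.
* The severity reference uses the median of projected Centiloid positions;
  at even n the midpoint convention differs infinitesimally from a median of
  predicted CSF values (monotonicity makes the orderings identical).
* No uncertainty quantification of the curve parameters is provided, by
  design; the identifiability caveat above explains why interval estimates
  for (a, b, c) would be misleading in the weakly identified regime.
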