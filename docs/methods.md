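# Methods

`grsmr` implements a one-sample genetic-risk-score (GRS) Mendelian
randomization (MR) analysis of blood pressure (BP) on categorical kidney
outcomes, together with the summary-data sensitivity battery used to probe
the instrumental-variable assumptions, a conventional observational
comparator with regression-dilution correction, and a synthetic biobank
generator whose parameters are the recoverable ground truth for every test
in the package.

## The estimand and the estimator

For a binary kidney outcome $Y$ (e.g. CKD, the composite of kidney
replacement therapy, eGFR < 60 mL/min/1.73m², or uACR ≥ 3 mg/mmol), the
one-sample estimator is the standard two-stage ratio:

1. logistic regression of $Y$ on the GRS $G = \sum_j w_j x_{ij}$ with
   covariates age, age², sex, BMI, 18 principal components and genotyping
   array, giving $\hat\beta_{GY}$ (log-odds per score unit);
2. linear "calibration" regression of measured, treatment-adjusted BP on
   the same score and covariates, giving $\hat\beta_{GX}$ (mmHg per score
   unit);
3. reported effect $= u \,\hat\beta_{GY}/\hat\beta_{GX}$ with $u = 10$ mmHg
   (systolic) or $5$ mmHg (diastolic), exponentiated to an odds ratio.

The default standard error scales the outcome-stage SE only
(`se_method="ratio"`), appropriate when the calibration t-statistic is
large; a delta-method option propagates first-stage error.  A warning is
attached when $|t| < 10$ for the calibration slope.

Categorical eGFR and uACR outcomes use multinomial logistic regression with
fixed references (eGFR 60–90; uACR < 3).  An eGFR ≥ 120 category is treated
as evidence of glomerular hyperfiltration, so a positive effect on both the
lowest and highest eGFR categories is the U-shape signature the analysis is
designed to detect.

## Summary-data sensitivity battery

Per-variant summary statistics are derived from the individual-level data:
exposure betas by exact covariate-adjusted OLS (Frisch–Waugh
residualization), outcome betas by a per-variant logistic fit with the
covariate-only linear predictor as an offset, vectorized across variants
(Newton–Raphson; an exact joint-fit path exists for verification — the two
agree to a small fraction of a standard error because genotypes are
independent of covariates).  For estimator input, the exposure side is then
replaced by the external instrument weights (`attach_external_weights`),
matching the design in which weights come from a large consortium GWAS: at
biobank scale, in-sample per-variant exposure estimates have F-statistics
low enough that IVW and Egger visibly dilute toward the null (the NOME
violation); external weights with GWAS-scale SEs restore the
no-measurement-error regime.

Estimators (per-allele scale; multiplied by 10 or 5 for reporting):

* **Wald ratio** $\beta_Y/\beta_X$, first-order SE $se_Y/|\beta_X|$.
* **IVW**: fixed-effect inverse-variance-weighted mean of ratios, equal to
  the zero-intercept WLS of $\beta_Y$ on $\beta_X$ with weights
  $1/se_Y^2$; Cochran's Q reported.
* **MR-Egger**: WLS with a free intercept after orienting all variants to
  $\beta_X > 0$; the intercept estimates average directional pleiotropy per
  variant and is exponentiated for odds-scale reporting (the per-allele
  convention is stated because no per-variant strength scaling is applied).
  SEs use a multiplicative residual scale truncated below at 1 and t
  inference on J−2 df; an $I^2_{GX} < 0.9$ diagnostic warns of
  weak-regression bias.
* **Weighted median**: linear interpolation of ordered ratios at cumulative
  normalized inverse-variance weight 0.5; SE by parametric bootstrap
  (default 1000 resamples, seeded).  Its robustness to <50% invalid weight
  is an asymptotic property: with finite summary SEs the estimate sits at
  the contamination-shifted quantile of the sampling scatter, so residual
  displacement is of the order of the ratio-level SE — the tests bound it
  accordingly.
* **Modified-Q filter**: iteratively removes the variant with the largest Q
  contribution while its χ²(1) p-value, Bonferroni-corrected over remaining
  variants, is below α (default 0.05); aborts rather than reducing the set
  below two variants.
* **MR-PRESSO**: observed statistic is the weighted RSS of leave-one-out
  IVW predictions; the null distribution simulates per-variant betas from
  their sampling distributions around the leave-one-out fits (default 1000
  draws, seeded).  The global p uses the (count+1)/(n+1) convention; the
  per-variant outlier p uses the raw empirical proportion so that
  Bonferroni can still flag an outlier at achievable resolution.  A
  distortion test contrasts raw and outlier-corrected estimates against
  random pseudo-outlier sets.
* **Steiger filter**: removes variants with strictly more outcome- than
  exposure-variance explained (squared dosage correlations; for kidney
  outcomes the continuous eGFR is the recommended Steiger outcome).
  Missing r² retains the variant with a warning.

## Conventional comparator and regression dilution

The conventional analysis regresses each outcome on measured BP adjusted
for age, sex, region, education, deprivation fifths, smoking, alcohol,
physical activity, diabetes and BMI fifths.  The regression-dilution ratio
(RDR) is the OLS slope of a resurvey measurement on the baseline
measurement among resurveyed participants (MacMahon-style); the log-odds
estimate and both CI limits are divided by the RDR.  Correction is applied
uniformly to binary and multinomial estimates, with an off switch.  A
small residual discrepancy (a few percent) between the corrected estimate
and the error-free oracle is expected from the non-linearity of the
logistic error-in-variables problem; the tests allow for it explicitly.

## The synthetic cohort generator

The generator emulates a middle-aged population biobank: age ~ N(57, 8²)
years, 46.5% male, BMI ~ N(27.4, 4.7²) kg/m², measured SBP 141.7 (20.6) and
DBP 84.6 (11.2) mmHg, 23.1% on antihypertensive treatment, CKD prevalence
6.95% (reduced eGFR 2.5%, albuminuria 5.0%, with the observed overlap),
hyperfiltration 0.59%, AKI hospitalization 3.25%, 219 systolic and 223
diastolic instruments explaining 1.6% and 2.1% of measured BP variance, 5%
resurveyed.  These are the package's study conditions and are not tuned
per-test.

Key design choices:

* **Instruments**: independent bi-allelic variants, MAF ~ U(0.05, 0.5),
  Hardy–Weinberg genotypes (no LD — instruments represent independent
  loci).  True per-allele effects are Gaussian, rescaled so
  $\sum_j 2p_j(1-p_j)a_j^2$ equals the target fraction of *measured* BP
  variance exactly; R² targets are defined against measured BP because that
  is the variance the score's published R² refers to.  Published weights
  are true effects plus Gaussian noise with the SE of a 750,000-sample
  GWAS; an exact-weights mode exists for oracle tests.  Each variant
  affects only its own trait (no cross-trait effects), which keeps the two
  scores mutually independent and each trait's causal pathway separately
  identifiable; the price is that cross-trait descriptive gradients (e.g. a
  diastolic-BP difference across systolic-GRS fifths) are absent from the
  synthetic cohort.  Because published instrument tables have already
  resolved strand ambiguity, the generator does not emit palindromic allele
  pairs at frequencies the harmonizer would drop.
* **Blood pressure**: usual (true) BP is built from age, sex, BMI, the
  genetic component and a bivariate-normal residual (SBP–DBP residual
  correlation 0.6).  Each clinic reading is usual BP plus independent
  error whose SD is derived from the requested regression-dilution ratio
  ($\sigma_e = \sqrt{2 V_{meas}(1-\mathrm{RDR})}$, so baseline = mean of
  two readings attenuates by exactly RDR).  Treatment is assigned by a
  logistic model on usual SBP (prevalence-calibrated) and subtracts
  15/10 mmHg from the observed readings only, so the +15/+10 analysis
  correction inverts it by construction.
* **Kidney outcomes** are hierarchical latent classes: CKD is Bernoulli
  with a logit linear in usual SBP/10 and DBP/5 (plus an optional direct
  BMI term, and per-variant pleiotropic terms), then manifested as
  reduced-eGFR / albuminuria / both in the observed proportions;
  hyperfiltration is Bernoulli among non-CKD with its own SBP pathway.
  eGFR is drawn from class-specific truncated normals (95/50/125 means,
  10/8/5 SDs, truncated at the clinical boundaries so categories track
  classes), and uACR from boundary-truncated lognormals with a log-linear
  SBP severity effect.  A flat three-class multinomial logit was
  considered; the hierarchical form was chosen because it makes the
  composite-CKD log-OR itself an exact model parameter rather than a
  derived, non-logistic marginal.  Serum creatinine and cystatin C are
  back-computed from each participant's eGFR along the ray
  scr = κ·t, scys = 0.8·t (closed-form inverse of the CKD-EPI equation),
  so the analysis-side derivation reproduces the intended categories.
* **Effect calibration**: causal parameters are specified on the reporting
  scale (log-odds per 10/5 mmHg) and interpreted as the GRS-identifiable
  estimand.  A logistic outcome marginalized over residual BP is mildly
  attenuated relative to its structural coefficient (a ~3–8% effect at
  these prevalences and residual SDs), so the generator solves the
  structural liability coefficients by Gauss–Hermite integration and a
  fixed-point iteration such that the requested value is what the
  covariate-adjusted scaled estimator converges to.  Both coefficients are
  stored in the truth object.
* **Planted violations**: pleiotropy adds per-allele log-odds directly to
  the CKD logit, balanced or directional *with respect to the BP-raising
  allele* (directional offsets planted on the effect allele regardless of
  sign would cancel after Egger's orientation step); "kidney" variants add
  a directional eGFR effect (for Steiger detection) plus a small aligned
  direct CKD effect (so filtering has a bias to remove); mediator variants
  shift BMI/WHR/T2D, which propagate to BP and (optionally) the outcome
  through the confounder coefficients.
* **CKD-EPI equation**: combined creatinine–cystatin coefficients
  (scale 135; κ = 0.7/0.9 and α = −0.248/−0.207 by sex; exponents −0.601,
  −0.375, −0.711; 0.995^age; ×0.969 female).  The race term is omitted:
  the generator emulates a single-ancestry cohort.

What the generator does **not** emulate: linkage disequilibrium, imputation
uncertainty, population stratification beyond noise PCs, relatedness,
longitudinal eGFR decline, assay batch effects, or non-random missingness.
Passing tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to those real-data features.

## Numerical choices

* Logistic and multinomial fits: statsmodels ML (Newton/IRLS), maxiter
  100–200; non-convergence raises a warning, never silently passes.
* Vectorized per-variant logistic: Newton with analytic 2×2 information,
  convergence 1e-8 on coefficients, max 12 iterations, chunked over
  variants to bound memory.
* Gauss–Hermite integration: 80 nodes; intercepts solved by Brent's method
  to 1e-12; calibration fixed point iterated to 1e-12.
* Palindromic-variant ambiguity window: effect-allele frequency in
  [0.42, 0.58] (configurable).
* Fifths: rank-based with stable tie-breaking, sizes equal to within one.
* Quintile trend tests: regression of the characteristic on the ordinal
  fifth index (logistic for binary characteristics).
* Missing dosages imputed at 2×EAF; participants with >10% missing dosages
  flagged.
* Multinomial reference categories are fixed (eGFR 60–90, uACR < 3);
  categories under the case floor (default 10) are reported not-estimable.
* All randomness flows from a single integer seed; sub-streams are derived
  with `numpy.random.default_rng([seed, stream])`.

## Problem sizes used by the test-suite and the acceptance script

Replicate-based calibration checks use 200 replicates of n = 20,000 with
200 systolic instruments; single-replicate structural checks (U-shape,
Steiger, dilution) use n = 60,000–100,000; the acceptance script's two
scenarios use n = 200,000.  These sizes were chosen so Monte-Carlo error is
small relative to the effects being recovered while a full run remains a
desk-scale computation.

## Known limitations

* The scaled-estimate SE ignores first-stage sampling error by default;
  with per-score-unit calibration t-statistics in the tens to hundreds this
  is negligible, but the delta option should be used with weak scores.
* The multivariable (mediator-adjusted) analysis uses individual-level
  predicted-mediator scores — the one-sample analogue of adjusting for
  external mediator GWAS effects — and is an interpretation, not a
  replication, of the two-sample construction.
* The Egger intercept is reported per allele; comparing it with intercepts
  reported under other instrument-strength scalings requires care.
* The conventional estimator's dilution correction is the single-ratio
  division; structural measurement-error models are out of scope.
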