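# Methods

This note documents the statistical models gripmr implements, the
assumptions behind them, the synthetic-data generator used to validate
them, and the numerical and design choices made where the methodology left
room.

## The scientific setting

Circulating 25-hydroxyvitamin D (25(OH)D, nmol/L) is the standard marker of
vitamin D status; maximum grip strength (kg) is a standard marker of muscle
strength. Cross-sectional associations between the two are vulnerable to
confounding (body composition, age, smoking, deprivation) and say nothing
about the *shape* of any causal effect — yet shape is exactly what matters
for supplementation policy: a gain confined to low-status individuals
behaves very differently from a uniform linear gain. gripmr therefore
triangulates three analyses: an observational dose–response model, a linear
Mendelian randomization (MR), and a nonlinear MR, all sex-stratified
because the grip-strength distribution differs markedly by sex.

## Fractional polynomials

All dose–response modelling uses fractional polynomials with the canonical
power set S = {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, power 0 denoting ln x and a
repeated power (p, p) contributing x^p and x^p·ln x. Degree-1 (8 models)
and degree-2 (36 models) families are searched exhaustively; the winner
minimizes the Gaussian deviance −2·logL = n(log(2π·RSS/n) + 1), with ties
broken toward the earlier (simpler) candidate in enumeration order.
Likelihood-ratio comparisons use the conventional degrees of freedom —
FP1 vs linear: 1, FP2 vs FP1: 2, FP2 vs linear: 3 — and χ² reference
distributions. Exposures enter in native nmol/L (no pre-scaling or
centering), so powers, coefficients and curves all live on the nmol/L
scale; this requires x > 0, guaranteed here by the assay floor.

The observational arm adjusts for calendar month of blood draw
(categorical), vitamin D supplementation, age, smoking status
(categorical), BMI and Townsend deprivation. The selection cascade follows
the standard closed procedure: best FP2 vs best FP1 fixes the degree; the
winner vs the straight line gives p_nonlinear, with p < .05 selecting the
curved model. Fitted models are summarised as mean-difference curves
D(x) = f(x) − f(50) on a default grid of 15–90 nmol/L; pointwise 95%
intervals come from the covariance of the FP-term coefficients through the
contrast b(x) − b(50). Covariate–FP coefficient covariance is deliberately
excluded: covariates are held fixed in the contrast, so only the FP block
contributes, and the interval has exactly zero width at the reference.
The age-stratified variant refits the pooled selected form within the four
fixed bands (<50, 50–59, 60–64, 65+, left-closed on integer ages) without
re-selecting powers — keeping the interaction test interpretable — and
tests interaction by comparing the pooled model (with band main effects)
against the model adding band × FP-term columns (df = 3 × number of FP
terms). Continuous age remains a covariate inside each band.

## Linear MR

The instrument is a weighted allele score, Z = Σ wⱼgⱼ / Σ wⱼ, the weighted
*average* of exposure-increasing allele dosages with discovery-GWAS effect
sizes (ln-25(OH)D scale) as weights. Any SNP listed with a negative weight
is re-oriented at load time (dosage flipped, frequency complemented), so
weights are always positive. The average (rather than sum) convention
affects first-stage coefficients but cancels in every MR ratio.

The causal estimate is the Wald ratio β = β_ZY/β_ZX from regressions of
outcome and exposure on the score, both adjusted for the exposure's
determinants (month, supplementation) and 10 genetic principal components —
not for the behavioural confounders, which the instrument is meant to
bypass. With a single instrument the ratio coincides with two-stage least
squares, so the 2SLS-vs-ratio distinction is moot here (verified as an
algebraic identity in the tests). The delta-method standard error
se = se_ZY/|β_ZX| treats the denominator as fixed; this is accurate in the
very strong instrument regime the method targets (F in the thousands) and
a warning is emitted whenever F < 10, where the approximation is unsafe.
Estimates are reported per 25 nmol/L of genetically proxied 25(OH)D.
Instrument validity is probed by regressing each potential confounder on
the score (global F test for categorical confounders), with raw p-values
and no multiplicity adjustment; constant columns are flagged and excluded.

## Nonlinear MR: doubly-ranked LACE meta-regression

Participants are stably sorted by score (ties keep original row order) and
cut into consecutive pre-strata of size K; within each pre-stratum,
stable-sorted by exposure, the j-th ranked individual joins stratum j.
Each of the K strata then spans a different exposure level while holding a
comparable score distribution, so stratum-specific IV estimation is valid.
When K does not divide N the final incomplete pre-stratum is dropped (and
logged); with N ≫ K this loses at most K − 1 rows. Complete strata have
exactly ⌊N/K⌋ members; strata smaller than 30 (or than the covariate
design) are refused with advice to lower K rather than silently pooled.

The localized average causal effect in stratum j is
LACE_j = β_ZY(stratum j)/β_ZX with the denominator estimated once in the
whole analysed sample — the default, matching the method's standard
description — and se(LACE_j) = se_ZY,j/|β_ZX|, the denominator treated as
fixed (a warning fires if the population F < 100). A `denominator="stratum"`
switch estimates the first stage within each stratum instead.

The denominator choice matters more than it first appears. Because the
score acts multiplicatively on exposure (weights live on the log scale),
dX/dZ is larger in high-exposure strata; the population-denominator LACE
therefore estimates h′(x) scaled by roughly x/x̄ — attenuated at low
exposure, amplified at high exposure — whereas the stratum-denominator LACE
estimates h′(x) itself. Shape-recovery validation against generator truth
accordingly uses the stratum denominator; the population default is kept
for fidelity to the method's published form, and the two agree whenever the
instrument–exposure coupling is homogeneous.

Since each LACE estimates the slope h′ at its stratum's mean exposure, the
meta-regression fits LACE_j on the *derivative* of the FP basis evaluated
at mean exposures, by weighted least squares with inverse-variance weights
and no free intercept (the intercept of h has zero derivative; the power-1
term supplies the constant-slope column, so the linear causal model is the
FP family member with p = 1). Variances are treated as known: deviance is
the weighted RSS and the coefficient covariance is (BᵀWB)⁻¹. The FP test
for nonlinearity compares the best FP1 against the constant-slope model
(χ²₁). For the reported curve, the best FP2 replaces the best FP1 when it
wins their LR comparison (df 2). The selected derivative model is
integrated in closed form — each derivative-basis column has the
corresponding FP term as antiderivative — giving h(x) − h(50) with
intervals from the same coefficient covariance, exactly zero at the
reference. `NonlinearMRResult.protocol_curve()` returns the curve the
analysis protocol actually reports: the FP curve when the nonlinearity
test rejects, otherwise the constant-slope (linear-MR) curve, mirroring
the fallback to linear MR.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume,
calibrated to large-cohort summary statistics; defaults live in
`gripmr/data/ukb_like.yaml`.

* **Covariates.** Sex (46.7% male), integer age uniform on 37–73, month
  uniform on 1–12, supplementation Bernoulli(6.5%), smoking
  never/previous/current (55/35/10%), BMI ~ N(27.4, 4.7²), Townsend
  ~ N(−1.55, 2.9²), 10 standard-normal principal components. The
  confounder marginals use simple parametric families; only their joint
  effects on exposure and outcome matter downstream.
* **Genotypes.** Binomial(2, freq) per SNP in linkage equilibrium,
  mirroring an LD-clumped instrument; the packaged 6-SNP file is a
  synthetic stand-in with weights on the published GWAS scale.
* **Exposure.** ln X is a linear predictor in the standardized score, a
  seasonal sinusoid peaking in July (amplitude 8 nmol/L, divided by the
  exposure mean for the log scale), supplementation (+10 nmol/L
  equivalent), confounder terms and unit Gaussian noise. The predictor is
  standardized empirically and mapped onto the log-normal (μ, σ) implied
  by the target mean and SD (49.9, 21.1), so realised moments track the
  targets at large n; X is floored at the 10 nmol/L assay limit.
  Generating on the log scale keeps X > 0 (the FP bases require it) and
  makes the score multiplicative, consistent with log-scale GWAS weights.
  The score coefficient is then solved by Brent root-finding so the
  realised score R² for X equals `target_score_r2` (default 2.5%); an
  unattainable target raises a configuration error.
* **Outcome.** Y = sex-specific intercept + causal_fn(X) + confounder
  terms + Gaussian noise, with intercept and noise SD solved per sex from
  the realised structural variance so means and SDs hit the targets
  (41.9 (8.9) / 25.2 (6.3) kg); Y is floored at 0.1 kg (recorded grip is
  strictly positive). Causal functions: null, linear(slope), plateau(slope
  below a knot, flat above) and single-FP shapes; optional per-age-band
  effect multipliers create age × exposure interaction, and an optional
  score→BMI leak plants a pleiotropic path for testing the confounder
  scan.
* **Confounder effects** (per SD of confounder): BMI −0.20 on the
  log-exposure predictor and +1.0 kg on grip; age −0.10 and −2.5 kg;
  current smoking −0.15 and −0.8 kg; Townsend −0.10 and −0.3 kg. These
  produce a crude observational exposure–outcome slope biased by many
  standard errors under a null causal effect — the signature MR is meant
  to remove — while leaving the MR estimand clean. The magnitudes are
  package choices on the scale of reported epidemiological associations;
  the source analyses publish no confounder path coefficients.
* **Determinism.** One RNG stream with a fixed draw order; identical
  (config, instrument) inputs give bit-identical tables.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, missing data, selection/collider effects, assay measurement error
beyond the floor, and non-Gaussian outcome tails. Passing tests therefore
demonstrate correctness of the estimators under the stated structure, not
robustness to those real-data features.

## Numerical choices

OLS uses a Cholesky solve of the normal equations with the unbiased
residual variance in the coefficient covariance; a failed factorization
raises a singular-fit error. Exact-fit deviances guard RSS below 1e-300
before the log. Negative LR statistics (roundoff) are clamped to zero.
Meta-regression requires ≥10 strata with finite standard errors and
refuses an all-equal mean-exposure design. Curve grids must be strictly
positive; a reference outside the observed exposure range warns.

## Validation design and known limitations

Monte-Carlo checks run at sizes chosen to keep the default suite fast:
type-I error of both nonlinearity tests over 200 replicates of n = 20,000
(observed 3.5% and 4.0% at nominal 5%); plateau-shape power over 20
replicates of n = 200,000 with slope 0.06 — chosen by a power analysis
targeting ≥90% rejection given the calibrated instrument strength —
and curve coverage over 30 replicates with correspondingly slackened
binomial thresholds.

Two limitations deserve emphasis. First, smooth FP families cannot
represent a hard kink: fitted to a threshold truth they round the corner,
understating the deficit just below the knot and integrating residual
positive slope above it (≈ 0.2 × slope × 25 kg over the 50→75 nmol/L
segment), an approximation bias that can exceed the pointwise interval
width at large n. Second, post-selection inference: intervals for the
best-fitting FP ignore the power search, and under a linear truth the
FP1-selected curve undercovers; the protocol curve (with its linear
fallback) restores near-nominal coverage and is the recommended summary.
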