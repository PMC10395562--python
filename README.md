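# gripmr

Dose–response analysis of circulating 25-hydroxyvitamin D (25(OH)D) and
maximum grip strength, for epidemiologists studying whether vitamin D status
causally influences muscle strength — and, crucially, whether the
relationship is nonlinear (a gain confined to people with low status would
make supplementation targeting worthwhile; a uniform linear gain would not).

The package implements three complementary analyses over a participant
table (25(OH)D in nmol/L, grip strength in kg, covariates, and genotype
dosages or a precomputed allele score):

1. **Observational arm** — sex-stratified, covariate-adjusted
   fractional-polynomial (FP) regression of grip on 25(OH)D. Powers are
   drawn from S = {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 ≡ ln x; a repeated
   power p contributes x^p and x^p·ln x). The best FP1 and FP2 are found by
   exhaustive search; likelihood-ratio tests fix the degree and test
   nonlinearity against the straight line. Results are reported as
   mean-difference curves anchored at a reference (50 nmol/L), plus an
   age-stratified variant (<50, 50–59, 60–64, 65+) with an interaction
   test.
2. **Linear Mendelian randomization** — a weighted allele score
   Z = Σⱼ wⱼ gⱼ / Σⱼ wⱼ (GWAS weights on the ln-25(OH)D scale, alleles
   oriented to increase exposure) is used as a single instrument. The
   estimate is the Wald ratio β = β_ZY / β_ZX of covariate-adjusted
   score-outcome and score-exposure coefficients (identical to 2SLS with
   one instrument), reported in kg per 25 nmol/L, with first-stage R² and
   F diagnostics and a score-vs-confounder pleiotropy scan.
3. **Nonlinear MR** — the doubly-ranked method: participants are ranked by
   score into pre-strata of size K, then dealt to K strata by
   within-pre-stratum exposure rank (default K = 100). Each stratum j
   yields a localized average causal effect, LACE_j = β_ZY(stratum j) /
   β_ZX, the causal slope h′ at that stratum's mean exposure. A weighted FP
   meta-regression of LACE on stratum mean 25(OH)D estimates h′(x); the FP
   test compares the best FP1 against the constant-slope model (χ²₁); the
   selected model is integrated in closed form to the causal curve
   h(x) − h(50). When the FP test does not reject, the linear MR estimate
   is the headline result.

Because the individual-level cohort data such analyses run on are access
restricted, the package ships a first-class synthetic cohort generator
(`gripmr.simulate`) calibrated to published summary statistics — 25(OH)D
≈ 49.9 (21.1) nmol/L with seasonal/supplementation structure and a 10
nmol/L assay floor, grip ≈ 41.9 (8.9) kg in males and 25.2 (6.3) kg in
females, a 6-SNP score explaining ≈2.5% of exposure variance, and shared
confounding by BMI, age, smoking and deprivation — with configurable true
causal functions (null, linear, plateau, FP-shaped) so every method can be
validated against known ground truth.

## Worked example

```sh
python examples/nonlinear_mr.py
```

generates 200,000 participants with a threshold truth — grip rises by
0.06 kg per nmol/L of 25(OH)D below 50 nmol/L and not at all above — and
runs the full nonlinear MR pipeline:

```
strata: 100 of 2000 participants each (0 remainder rows dropped)
first-stage R^2 = 2.51%, F = 5204
mean LACE below 40 nmol/L: +0.049 kg/nmol/L (truth +0.060)
mean LACE above 65 nmol/L: +0.012 kg/nmol/L (truth  0.000)
FP nonlinearity test (best FP1 vs linear): p = 0.0170
selected meta-regression: meta_fp1 powers (0.0,)
causal difference at 25 vs 50 nmol/L: -1.05 kg (95% CI -1.45, -0.65)
causal difference at 75 vs 50 nmol/L: +0.61 kg (95% CI +0.38, +0.85)
linear MR fallback: +0.75 kg per 25 nmol/L (95% CI +0.46, +1.04) — the headline
estimate whenever the FP test does not reject
```

Reading the output: stratum-level causal slopes track the true local slope
(≈0.06 below the threshold, ≈0 above); the FP test correctly rejects a
constant slope; and the integrated curve shows a ~1 kg deficit at 25 nmol/L
against the 50 nmol/L reference. The smooth FP family rounds the sharp kink
at 50, so some of the below-threshold gain spills into the 50→75 segment —
a documented limitation (see `docs/methods.md`).

The other examples cover cohort simulation and calibration
(`examples/simulate_cohort.py`), the observational FP arm with the
age-interaction test (`examples/observational_dose_response.py`), and
linear MR with confounded observational contrast and pleiotropy scan
(`examples/linear_mr.py`). A thin CLI wraps the same pipelines for
file-based use:

```sh
gripmr simulate --out sim/ --n 50000 --seed 1
gripmr observational --cohort sim/cohort.tsv --sex male --out results/
gripmr mr-linear --cohort sim/cohort.tsv --weights sim/instrument.tsv --sex male --out results/
gripmr mr-nonlinear --cohort sim/cohort.tsv --sex male --strata 100 --out results/
```

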