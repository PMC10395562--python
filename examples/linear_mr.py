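"""Linear Mendelian randomization with the weighted allele score.

The cohort carries a true linear effect of 0.01 kg per nmol/L (0.25 kg per
25 nmol/L) and strong confounding of exposure and outcome by BMI, age,
smoking and deprivation.  The crude observational slope is biased; the MR
estimate — the Wald ratio of score-outcome to score-exposure coefficients,
adjusted for month, supplementation and genetic principal components — is
not.  The confounder scan checks the instrument for pleiotropy.
"""

import numpy as np

from gripmr import confounder_scan, default_config, run_linear_mr, simulate_cohort

cfg = default_config(n=100_000, seed=3)
cohort = simulate_cohort(cfg)

males = cohort[cohort.sex == "male"]
crude = np.polyfit(males["exposure"], males["outcome"], 1)[0] * 25.0
print(f"crude observational slope (males): {crude:+.2f} kg per 25 nmol/L "
      f"(truth 0.25; biased by shared confounders)")

mr = run_linear_mr(cohort, sex="male")
print(f"linear MR (males): {mr.beta_per_25:+.2f} kg per 25 nmol/L "
      f"(95% CI {mr.ci95[0]:+.2f}, {mr.ci95[1]:+.2f})")
print(f"instrument strength: R^2 = {mr.first_stage_r2:.2%}, "
      f"F = {mr.f_statistic:.0f} (weak-instrument bias negligible)")

scan = confounder_scan(males["score"], males[["age", "bmi", "townsend", "smoking"]])
print("\nconfounder scan (score vs potential confounders, raw p-values):")
for row in scan.itertuples(index=False):
    print(f"  {row.confounder:<10} {row.type:<12} p = {row.p:.3f}")
print("Uniform-looking p-values are the expected signature of a valid, "
      "pleiotropy-free instrument.")
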