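"""Cross-sectional fractional-polynomial dose-response analysis.

A male cohort is generated with a threshold ("plateau") truth: grip strength
gains 0.04 kg per nmol/L of 25(OH)D below 50 nmol/L and nothing above it.
The analysis adjusts for month of blood draw, supplementation, age, smoking,
BMI and deprivation, picks the best fractional polynomial by likelihood
ratio, and prints the mean-difference curve anchored at 50 nmol/L — the
true differences are -1.0 kg at 25 nmol/L and 0.0 kg at 75 nmol/L.
"""

from gripmr import PlateauEffect, default_config, run_observational, simulate_cohort

cfg = default_config(
    n=60_000, seed=7, sex_fraction_male=1.0,
    causal_fn=PlateauEffect(slope=0.04, knot=50.0),
)
cohort = simulate_cohort(cfg)
res = run_observational(cohort, sex="male", reference=50.0)

print(f"n = {res.n} males; selected model: {res.fit.family} "
      f"powers {res.fit.powers}")
print(f"nonlinearity test (best FP vs linear): "
      f"chi2({res.p_nonlinear.df}) = {res.p_nonlinear.statistic:.1f}, "
      f"p = {res.p_nonlinear.p:.2e}")
for x in (25.0, 40.0, 75.0):
    d, lo, hi = res.curve.at(x)
    print(f"grip difference at {x:.0f} vs 50 nmol/L: "
          f"{d:+.2f} kg (95% CI {lo:+.2f}, {hi:+.2f})")
print("A negative difference below 50 nmol/L with little change above it "
      "reproduces the threshold shape (smooth polynomials round the kink).")

# age-stratified curves and the interaction test
from gripmr import run_age_stratified

ages = run_age_stratified(cohort, "male", pooled=res)
print(f"age x 25(OH)D interaction: p = {ages.interaction.p:.3f} "
      f"(no age-modification was simulated)")
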