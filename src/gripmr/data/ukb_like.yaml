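# Default 'ukb_like' simulation configuration: a synthetic cohort calibrated
# to large-cohort summary statistics for 25(OH)D (nmol/L) and maximum grip
# strength (kg), with a linear true causal effect of 0.01 kg per nmol/L
# (0.25 kg per 25 nmol/L) and shared confounding of exposure and outcome.
n: 200000
seed: 2026
sex_fraction_male: 0.467
causal_fn: {kind: linear, slope: 0.01}
target_score_r2: 0.025
exposure_mean: 49.9
exposure_sd: 21.1
outcome_mean_male: 41.9
outcome_sd_male: 8.9
outcome_mean_female: 25.2
outcome_sd_female: 6.3
confounder_effects:
  bmi: [-0.20, 1.0]
  age: [-0.10, -2.5]
  smoking: [-0.15, -0.8]
  townsend: [-0.10, -0.3]
season_amplitude: 8.0
supplement_prevalence: 0.065
supplement_effect: 10.0
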