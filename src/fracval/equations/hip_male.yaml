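# Toy 10-year hip fracture equation, men (illustrative coefficients only).
schema_version: 1
name: toy-hip-men
outcome: hip
sex: male
baseline_survival_10y: 0.991
continuous_terms:
  - {covariate: entry_age, scale: 10.0, power: 2.0, coefficient: 0.052, center: 36.0}
  - {covariate: bmi, scale: 5.0, power: 1.0, coefficient: -0.080, center: 5.42}
categorical_terms:
  smoking:
    non_smoker: 0.0
    ex_smoker: 0.05
    light: 0.10
    moderate: 0.18
    heavy: 0.30
    amount_not_recorded: 0.12
  alcohol:
    none: 0.0
    lt1: 0.0
    "1_2": 0.05
    "3_6": 0.18
    "7_9": 0.35
    gt9: 0.50
  ethnicity:
    white: 0.0
    indian: -0.20
    pakistani: -0.20
    bangladeshi: -0.20
    other_asian: -0.15
    black_caribbean: -0.30
    black_african: -0.30
    chinese: -0.25
    other: -0.15
binary_terms:
  prior_fracture: 0.60
  history_of_falls: 0.50
  rheumatologic_disease: 0.30
  dementia: 0.35
  malignancy: 0.10
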