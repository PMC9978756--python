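# Toy 10-year major osteoporotic fracture equation, men (illustrative
# coefficients only; see the female file for conventions).
schema_version: 1
name: toy-mof-men
outcome: major_osteoporotic
sex: male
baseline_survival_10y: 0.970
continuous_terms:
  - {covariate: entry_age, scale: 10.0, power: 2.0, coefficient: 0.034, center: 36.0}
  - {covariate: bmi, scale: 5.0, power: 1.0, coefficient: -0.050, center: 5.42}
categorical_terms:
  smoking:
    non_smoker: 0.0
    ex_smoker: 0.05
    light: 0.10
    moderate: 0.15
    heavy: 0.25
    amount_not_recorded: 0.10
  alcohol:
    none: 0.0
    lt1: 0.0
    "1_2": 0.05
    "3_6": 0.15
    "7_9": 0.30
    gt9: 0.45
  ethnicity:
    white: 0.0
    indian: -0.15
    pakistani: -0.15
    bangladeshi: -0.15
    other_asian: -0.10
    black_caribbean: -0.20
    black_african: -0.20
    chinese: -0.20
    other: -0.10
binary_terms:
  prior_fracture: 0.55
  history_of_falls: 0.40
  rheumatologic_disease: 0.35
  dementia: 0.25
  malignancy: 0.10
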