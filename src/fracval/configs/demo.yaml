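# Demonstration configuration: identical hazards to the default, but entry
# ages uniform over [30, 100) so old age bands carry enough person-time for
# per-band calibration, and no missingness (the demo focuses on the two
# calibration mechanisms, not on imputation).
schema_version: 1
study_start: 2004-01-01
study_end: 2016-03-31
age_band_edges: [30, 40, 50, 60, 70, 80, 90, 100]
fracture_base_hazard:
  female: [0.0012, 0.0020, 0.0040, 0.0080, 0.0160, 0.0300, 0.0450]
  male:   [0.0012, 0.0013, 0.0018, 0.0030, 0.0065, 0.0130, 0.0200]
death_base_hazard:
  female: [0.0006, 0.0015, 0.0035, 0.0080, 0.0250, 0.0750, 0.1800]
  male:   [0.0010, 0.0022, 0.0050, 0.0120, 0.0350, 0.1000, 0.2000]
dereg_hazard: 0.02
entry_age_beta: [1.0, 1.0]
female_fraction: 0.506
covariate_log_hrs:
  prior_fracture: 0.55
  rheumatologic_disease: 0.35
  history_of_falls: 0.40
death_covariate_log_hrs: {}
source_probs:
  gp_only: 0.72
  hospital_involved: 0.25
  death_certificate: 0.03
hospital_gp_overlap: 0.4
fracture_kind_probs:
  hip: 0.38
  distal_forearm: 0.32
  proximal_humerus: 0.14
  vertebral: 0.16
missingness: {}
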