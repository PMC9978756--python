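# File format contracts

All files are delimited text (CSV) or YAML/JSON. Dates are ISO `YYYY-MM-DD`;
times are years with 6 decimal places where exported.

## Cohort directory (`subjects.csv`, `events.csv`, `manifest.json`)

`subjects.csv` — one row per person:

| column | type | notes |
|---|---|---|
| `id` | int | unique key |
| `sex` | `female` / `male` | |
| `entry_age` | float years | in [30, 100) |
| `entry_date` | date | within the study window |
| `bmi` | float kg/m² | empty when not recorded |
| `smoking` | category | `non_smoker`, `ex_smoker`, `light`, `moderate`, `heavy`, `amount_not_recorded`; empty when not recorded |
| `alcohol` | category | `none`, `lt1`, `1_2`, `3_6`, `7_9`, `gt9`; empty when not recorded |
| `ethnicity` | category | `white`, `indian`, `pakistani`, `bangladeshi`, `other_asian`, `black_caribbean`, `black_african`, `chinese`, `other`; empty scores as `white` |
| `prior_fracture` | 0/1 | fracture recorded before entry |
| 17 Charlson condition flags + `history_of_falls` | 0/1 | absent ⇒ 0 |

`events.csv` — one row per dated, source-tagged record:

| column | type | notes |
|---|---|---|
| `subject_id` | int | |
| `date` | date | on/after the subject's entry |
| `kind` | `hip`, `distal_forearm`, `proximal_humerus`, `vertebral`, `nonfracture_death`, `deregistration` | |
| `sources` | `gp`, `hospital`, `death_cert` | one source per row; one fracture may appear as several same-dated rows |

`manifest.json` — stage name, seed, `config_hash` (SHA-256 prefix of the
canonical config YAML), `study_end`.

## Hazard configuration (YAML)

See `src/fracval/configs/default.yaml` for a fully commented example.  Keys:
`age_band_edges`, `fracture_base_hazard` / `death_base_hazard` (per sex,
per band, events/person-year), `dereg_hazard`, `covariate_log_hrs`,
`death_covariate_log_hrs`, `source_probs` (`gp_only`, `hospital_involved`,
`death_certificate`), `hospital_gp_overlap`, `fracture_kind_probs`,
`study_start`, `study_end`, `entry_age_beta`, `female_fraction`,
`missingness`, plus optional covariate-distribution overrides.

## Risk equation (YAML, `schema_version: 1`)

Keys: `name`, `outcome` (`major_osteoporotic` / `hip`), `sex`,
`baseline_survival_10y` in (0, 1), `continuous_terms` (list of `covariate`,
`coefficient`, `scale`, `power`, `log`, `center` — `power: 0` means
`ln(x/scale)`, the `log` flag multiplies by an extra `ln(x/scale)`),
`categorical_terms` (full level maps; one level must carry coefficient
exactly 0), `binary_terms`.  See `src/fracval/equations/*.yaml`.

## Follow-up table

`subject_id`, `time` (years, strictly positive, 6 dp), `cause`
(`fracture` / `death` / `censored`), `fracture_kind` (empty unless
`cause=fracture`).

## Validation report directory

* `discrimination_<outcome>_<sex>.csv` — one row per analysis population
  (`all`; age bands 30-64/65-74/75-84/85-99; Charlson 0/1/2/3+):
  `n`, `events`, `n_pairs`, `harrell_c` (+ CI), `d_stat` (+ CI),
  `r2_d` (+ CI), `available`.
* `calibration_<outcome>_<sex>_<type>_<group>.csv` — `decile` (1-10), `n`,
  `mean_predicted`, `observed_km`, `observed_aj`.
* `manifest.json` — seed, horizon, m, equations used, config hash.

## Imputation directory

`subjects_imp<j>.csv` (completed cohorts, j = 1..m) plus
`imputation_manifest.json` (m, seed, iterations, file list).
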