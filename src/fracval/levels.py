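"""Shared vocabulary: category level sets, condition flags, Charlson weights.

These level sets define the contract between the synthetic cohort, the risk
equation schema and the imputation models.  Categorical covariates carry a
"missing" state represented as ``None``/``NaN`` in tables; the recorded levels
below never include a missing placeholder.
"""

from __future__ import annotations

SEXES = ("female", "male")

#: Recorded smoking levels (a seventh state, "not recorded", is represented as
#: missing and handled by imputation).
SMOKING_LEVELS = (
    "non_smoker",
    "ex_smoker",
    "light",            # <10 cigarettes/day
    "moderate",         # 10-19 cigarettes/day
    "heavy",            # >=20 cigarettes/day
    "amount_not_recorded",  # current smoker, amount unknown
)

#: Recorded alcohol consumption levels (units/day).
ALCOHOL_LEVELS = (
    "none",
    "lt1",
    "1_2",
    "3_6",
    "7_9",
    "gt9",
)

#: Self-reported ethnic group; a missing value is treated as the reference
#: ("white") at prediction time, mirroring routine-data convention.
ETHNICITY_LEVELS = (
    "white",
    "indian",
    "pakistani",
    "bangladeshi",
    "other_asian",
    "black_caribbean",
    "black_african",
    "chinese",
    "other",
)

#: The 17 Charlson conditions with the original weight set (1/2/3/6),
#: no age adjustment.
CHARLSON_WEIGHTS = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "copd": 1,
    "rheumatologic_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes": 1,
    "diabetes_with_complications": 2,
    "hemiplegia": 2,
    "renal_disease": 2,
    "malignancy": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumour": 6,
    "aids": 6,
}

CHARLSON_CONDITIONS = tuple(CHARLSON_WEIGHTS)

#: Non-Charlson binary flags the simulator also generates (used by risk
#: equations but not by the comorbidity score).
EXTRA_FLAGS = ("history_of_falls",)

CONDITION_FLAGS = CHARLSON_CONDITIONS + EXTRA_FLAGS

#: Binary covariates a risk equation may reference.
BINARY_COVARIATES = CONDITION_FLAGS + ("prior_fracture",)

#: Continuous covariates a risk equation may reference.
NUMERIC_COVARIATES = ("entry_age", "bmi")

CATEGORICAL_LEVELS = {
    "smoking": SMOKING_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
}

FRACTURE_KINDS = ("hip", "distal_forearm", "proximal_humerus", "vertebral")
EVENT_KINDS = FRACTURE_KINDS + ("nonfracture_death", "deregistration")
SOURCES = ("gp", "hospital", "death_cert")

#: Composite membership per modelled outcome.
OUTCOME_KINDS = {
    "major_osteoporotic": FRACTURE_KINDS,
    "hip": ("hip",),
}
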