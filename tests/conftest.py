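import numpy as np
import pandas as pd
import pytest

import fracval as fv
from fracval.levels import CONDITION_FLAGS


def make_subjects(rows):
    """Build a subject table from partial dicts, filling neutral defaults."""
    defaults = {
        "sex": "female", "entry_age": 60.0,
        "entry_date": pd.Timestamp("2005-01-01"), "bmi": 26.6,
        "smoking": "non_smoker", "alcohol": "none", "ethnicity": "white",
        "prior_fracture": 0,
    }
    defaults.update({c: 0 for c in CONDITION_FLAGS})
    out = []
    for i, row in enumerate(rows):
        rec = {"id": i, **defaults, **row}
        out.append(rec)
    df = pd.DataFrame(out)
    df["entry_date"] = pd.to_datetime(df["entry_date"])
    return df


@pytest.fixture(scope="session")
def default_cfg():
    return fv.default_config()


@pytest.fixture(scope="session")
def cohort20k(default_cfg):
    return fv.simulate_cohort(default_cfg, 20000, seed=42)


@pytest.fixture(scope="session")
def followups20k(default_cfg, cohort20k):
    subjects, events = cohort20k
    return fv.determine_outcomes(subjects, events, "major_osteoporotic",
                                 study_end=default_cfg.study_end)


@pytest.fixture()
def subject_factory():
    return make_subjects


def competing_exponential(n, lam_frac, lam_death, seed):
    """Tie-free competing exponential draws (no censoring)."""
    rng = np.random.default_rng(seed)
    lam = lam_frac + lam_death
    t = rng.exponential(1.0 / lam, size=n)
    cause = np.where(rng.random(n) < lam_frac / lam, "fracture", "death")
    return t, cause.astype(object)
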