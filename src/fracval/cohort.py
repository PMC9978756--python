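"""Synthetic linked-cohort generator with competing fracture and mortality hazards.

The generator emulates the statistical structure an external validation of a
10-year fracture risk equation relies on, without any claim of equivalence to
real primary-care data:

* cause-specific hazards for major osteoporotic fracture and for death from
  non-fracture causes, piecewise-constant over age bands, both rising with age
  and with the death/fracture ratio growing much faster in men;
* calendar entry uniform over a fixed study window with administrative
  censoring at the window end, plus a constant deregistration hazard;
* covariate effects (log hazard ratios) acting on the fracture cause, with an
  optional separate set acting on death;
* multi-source recording of fracture events (general practice, hospital
  discharge, death certificate), enabling ascertainment-restriction
  experiments;
* missingness in BMI, smoking, alcohol and ethnicity, either completely at
  random or with logistic dependence on entry age.

Event times are sampled exactly by competing exponential draws within each
age band a subject traverses (no numerical inversion).  A subject has at most
one true fracture event, but after a fracture the death/deregistration
processes keep running so that analyses which discard that fracture (for
example source-restricted ascertainment) still see the subject's later
follow-up.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import ConfigError, DataError
from .levels import (
    ALCOHOL_LEVELS,
    BINARY_COVARIATES,
    CONDITION_FLAGS,
    ETHNICITY_LEVELS,
    FRACTURE_KINDS,
    SEXES,
    SMOKING_LEVELS,
)

DAYS_PER_YEAR = 365.25

SOURCE_PATTERNS = ("gp_only", "hospital_involved", "death_certificate")

#: Fields apply_missingness may blank.
MASKABLE_FIELDS = ("bmi", "smoking", "alcohol", "ethnicity")

SUBJECT_COLUMNS = (
    ("id", "sex", "entry_age", "entry_date", "bmi", "smoking", "alcohol",
     "ethnicity", "prior_fracture") + CONDITION_FLAGS
)

EVENT_COLUMNS = ("subject_id", "date", "kind", "sources")


@dataclasses.dataclass
class HazardConfig:
    """Generative configuration for :func:`simulate_cohort`.

    Rates are events per person-year.  ``age_band_edges`` must be strictly
    increasing, start at 30 and end at 100; hazards in the last band also
    apply to any follow-up beyond age 100.
    """

    age_band_edges: list
    fracture_base_hazard: dict      # sex -> per-band rate
    death_base_hazard: dict         # sex -> per-band rate
    dereg_hazard: float
    covariate_log_hrs: dict         # binary covariate -> log HR on fracture
    death_covariate_log_hrs: dict   # binary covariate -> log HR on death
    source_probs: dict              # recording-source pattern -> probability
    hospital_gp_overlap: float      # P(same-day gp record | hospital_involved)
    fracture_kind_probs: dict       # fracture kind -> probability
    study_start: pd.Timestamp
    study_end: pd.Timestamp
    entry_age_beta: tuple = (1.4, 3.2)
    female_fraction: float = 0.506
    bmi_params: dict = dataclasses.field(
        default_factory=lambda: {"female": (26.6, 6.0), "male": (27.1, 4.8)})
    smoking_probs: dict = None
    alcohol_probs: dict = None
    ethnicity_probs: dict = None
    prior_fracture_p60: float = 0.05
    condition_p60: dict = None      # condition flag -> prevalence at age 60
    condition_age_slope: float = 0.6   # log-odds per decade of entry age
    missingness: dict = dataclasses.field(default_factory=dict)

    def n_bands(self) -> int:
        return len(self.age_band_edges) - 1

    def validate(self) -> None:
        edges = np.asarray(self.age_band_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ConfigError("age_band_edges: need at least two edges")
        if not np.all(np.diff(edges) > 0):
            raise ConfigError("age_band_edges: edges must be strictly increasing")
        if edges[0] != 30 or edges[-1] != 100:
            raise ConfigError("age_band_edges: bands must cover [30, 100)")
        for name, table in (("fracture_base_hazard", self.fracture_base_hazard),
                            ("death_base_hazard", self.death_base_hazard)):
            for sex in SEXES:
                rates = np.asarray(table.get(sex, []), dtype=float)
                if rates.size != self.n_bands():
                    raise ConfigError(
                        f"{name}[{sex}]: expected {self.n_bands()} rates, got {rates.size}")
                if np.any(rates < 0):
                    raise ConfigError(f"{name}[{sex}]: rates must be >= 0")
        if self.dereg_hazard < 0:
            raise ConfigError("dereg_hazard: must be >= 0")
        for cov in {**self.covariate_log_hrs, **self.death_covariate_log_hrs}:
            if cov not in BINARY_COVARIATES:
                raise ConfigError(f"covariate_log_hrs: unknown binary covariate {cov!r}")
        probs = [self.source_probs.get(p, None) for p in SOURCE_PATTERNS]
        if any(p is None or p < 0 for p in probs):
            raise ConfigError(
                f"source_probs: need non-negative probabilities for {SOURCE_PATTERNS}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("source_probs: probabilities must sum to 1")
        if not 0 <= self.hospital_gp_overlap <= 1:
            raise ConfigError("hospital_gp_overlap: must be a probability")
        kp = [self.fracture_kind_probs.get(k, None) for k in FRACTURE_KINDS]
        if any(p is None or p < 0 for p in kp) or abs(sum(kp) - 1.0) > 1e-9:
            raise ConfigError(
                f"fracture_kind_probs: need probabilities for {FRACTURE_KINDS} summing to 1")
        if pd.Timestamp(self.study_end) <= pd.Timestamp(self.study_start):
            raise ConfigError("study_end: must be after study_start")
        a, b = self.entry_age_beta
        if a <= 0 or b <= 0:
            raise ConfigError("entry_age_beta: shape parameters must be > 0")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigError("female_fraction: must be a probability")


# --------------------------------------------------------------------------
# configuration IO


def _as_timestamp(value) -> pd.Timestamp:
    return pd.Timestamp(value)


def load_hazard_config(path) -> HazardConfig:
    """Load a hazard configuration from YAML and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return hazard_config_from_dict(raw)


def hazard_config_from_dict(raw: dict) -> HazardConfig:
    known = {f.name for f in dataclasses.fields(HazardConfig)}
    unknown = set(raw) - known - {"schema_version"}
    if unknown:
        raise ConfigError(f"hazard config: unknown fields {sorted(unknown)}")
    raw = {k: v for k, v in raw.items() if k != "schema_version"}
    missing = {"age_band_edges", "fracture_base_hazard", "death_base_hazard",
               "dereg_hazard", "source_probs", "fracture_kind_probs",
               "study_start", "study_end"} - set(raw)
    if missing:
        raise ConfigError(f"hazard config: missing fields {sorted(missing)}")
    raw.setdefault("covariate_log_hrs", {})
    raw.setdefault("death_covariate_log_hrs", {})
    raw.setdefault("hospital_gp_overlap", 0.0)
    raw["study_start"] = _as_timestamp(raw["study_start"])
    raw["study_end"] = _as_timestamp(raw["study_end"])
    if "entry_age_beta" in raw:
        raw["entry_age_beta"] = tuple(raw["entry_age_beta"])
    if "bmi_params" in raw:
        raw["bmi_params"] = {k: tuple(v) for k, v in raw["bmi_params"].items()}
    cfg = HazardConfig(**raw)
    cfg.validate()
    return cfg


def save_hazard_config(config: HazardConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["study_start"] = str(pd.Timestamp(config.study_start).date())
    d["study_end"] = str(pd.Timestamp(config.study_end).date())
    d["entry_age_beta"] = list(config.entry_age_beta)
    if d.get("bmi_params"):
        d["bmi_params"] = {k: list(v) for k, v in d["bmi_params"].items()}
    d["schema_version"] = 1
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def _packaged_config(name: str) -> HazardConfig:
    text = resources.files("fracval").joinpath(f"configs/{name}.yaml").read_text()
    return hazard_config_from_dict(yaml.safe_load(text))


def default_config() -> HazardConfig:
    """The shipped default generative configuration.

    Tuned so that fracture incidence rises steeply with age and non-fracture
    mortality overtakes it from middle age, with a death/fracture incidence
    ratio of about 4 in women and about 10 in men at ages 90-99.
    """
    return _packaged_config("default")


def demo_config() -> HazardConfig:
    """Demo configuration: uniform entry ages (more elderly person-time) and
    no missingness, used by the end-to-end demonstration command."""
    return _packaged_config("demo")


# --------------------------------------------------------------------------
# simulation


def _sex_codes(sex: np.ndarray) -> np.ndarray:
    return (np.asarray(sex) == "male").astype(np.intp)


def _categorical_draw(rng, levels, probs, size):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(levels, dtype=object), size=size, p=p)


_DEFAULT_SMOKING = {
    "female": (0.5704, 0.1943, 0.0670, 0.0930, 0.0534, 0.0219),
    "male": (0.4486, 0.2444, 0.0700, 0.1058, 0.0879, 0.0432),
}
_DEFAULT_ALCOHOL = {
    "female": (0.2792, 0.4174, 0.2738, 0.0255, 0.0027, 0.0013),
    "male": (0.1746, 0.3018, 0.3683, 0.1243, 0.0207, 0.0104),
}
_DEFAULT_ETHNICITY = {
    "female": (0.9517, 0.0093, 0.0040, 0.0013, 0.0069, 0.0017, 0.0083, 0.0027, 0.0142),
    "male": (0.9524, 0.0101, 0.0046, 0.0019, 0.0066, 0.0015, 0.0077, 0.0021, 0.0132),
}
_DEFAULT_CONDITION_P60 = {
    "myocardial_infarction": 0.020, "congestive_heart_failure": 0.012,
    "peripheral_vascular_disease": 0.012, "cerebrovascular_disease": 0.020,
    "dementia": 0.010, "copd": 0.050, "rheumatologic_disease": 0.008,
    "peptic_ulcer_disease": 0.010, "mild_liver_disease": 0.002,
    "diabetes": 0.033, "diabetes_with_complications": 0.005,
    "hemiplegia": 0.002, "renal_disease": 0.011, "malignancy": 0.030,
    "moderate_severe_liver_disease": 0.001, "metastatic_solid_tumour": 0.004,
    "aids": 0.001, "history_of_falls": 0.042,
}


def _draw_subjects(config: HazardConfig, n: int, rng) -> pd.DataFrame:
    a, b = config.entry_age_beta
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male").astype(object)
    entry_age = 30.0 + 70.0 * rng.beta(a, b, size=n)
    window_days = int((pd.Timestamp(config.study_end)
                       - pd.Timestamp(config.study_start)).days)
    entry_offset = rng.integers(0, window_days, size=n)
    entry_date = pd.Timestamp(config.study_start) + pd.to_timedelta(entry_offset, unit="D")

    bmi = np.empty(n)
    smoking = np.empty(n, dtype=object)
    alcohol = np.empty(n, dtype=object)
    ethnicity = np.empty(n, dtype=object)
    smoking_probs = config.smoking_probs or _DEFAULT_SMOKING
    alcohol_probs = config.alcohol_probs or _DEFAULT_ALCOHOL
    ethnicity_probs = config.ethnicity_probs or _DEFAULT_ETHNICITY
    for s in SEXES:
        mask = sex == s
        k = int(mask.sum())
        mu, sd = config.bmi_params[s]
        bmi[mask] = np.clip(rng.normal(mu, sd, size=k), 14.0, 55.0)
        smoking[mask] = _categorical_draw(rng, SMOKING_LEVELS, smoking_probs[s], k)
        alcohol[mask] = _categorical_draw(rng, ALCOHOL_LEVELS, alcohol_probs[s], k)
        ethnicity[mask] = _categorical_draw(rng, ETHNICITY_LEVELS, ethnicity_probs[s], k)

    slope = config.condition_age_slope
    decades = (entry_age - 60.0) / 10.0
    prior_p = expit(logit(config.prior_fracture_p60) + slope * decades)
    prior_fracture = (rng.random(n) < prior_p).astype(np.int8)

    cond_p60 = config.condition_p60 or _DEFAULT_CONDITION_P60
    flags = {}
    for cond in CONDITION_FLAGS:
        p = expit(logit(cond_p60.get(cond, 0.0) or 1e-9) + slope * decades)
        flags[cond] = (rng.random(n) < p).astype(np.int8)

    data = {
        "id": np.arange(n, dtype=np.int64),
        "sex": sex,
        "entry_age": entry_age,
        "entry_date": entry_date,
        "bmi": bmi,
        "smoking": smoking,
        "alcohol": alcohol,
        "ethnicity": ethnicity,
        "prior_fracture": prior_fracture,
    }
    data.update(flags)
    return pd.DataFrame(data, columns=list(SUBJECT_COLUMNS))


def _linear_predictors(config: HazardConfig, subjects: pd.DataFrame):
    lp_f = np.zeros(len(subjects))
    lp_d = np.zeros(len(subjects))
    for cov, loghr in config.covariate_log_hrs.items():
        lp_f += float(loghr) * subjects[cov].to_numpy(dtype=float)
    for cov, loghr in config.death_covariate_log_hrs.items():
        lp_d += float(loghr) * subjects[cov].to_numpy(dtype=float)
    return lp_f, lp_d


def _simulate_event_times(config: HazardConfig, subjects: pd.DataFrame, rng):
    """Competing-exponential engine advancing band by band.

    Returns (frac_t, death_t, dereg_t) in years from entry; NaN where the
    event did not occur before administrative censoring.
    """
    n = len(subjects)
    edges = np.asarray(config.age_band_edges, dtype=float)
    n_bands = edges.size - 1
    base_f = np.stack([np.asarray(config.fracture_base_hazard[s], dtype=float)
                       for s in SEXES])
    base_d = np.stack([np.asarray(config.death_base_hazard[s], dtype=float)
                       for s in SEXES])
    sex_code = _sex_codes(subjects["sex"].to_numpy())
    lp_f, lp_d = _linear_predictors(config, subjects)
    rr_f, rr_d = np.exp(lp_f), np.exp(lp_d)

    entry_age = subjects["entry_age"].to_numpy(dtype=float)
    admin = ((pd.Timestamp(config.study_end) - subjects["entry_date"]).dt.days
             .to_numpy(dtype=float)) / DAYS_PER_YEAR

    age = entry_age.copy()
    t = np.zeros(n)
    frac_t = np.full(n, np.nan)
    death_t = np.full(n, np.nan)
    dereg_t = np.full(n, np.nan)
    fractured = np.zeros(n, dtype=bool)
    active = admin > 0

    while active.any():
        idx = np.flatnonzero(active)
        band = np.clip(np.searchsorted(edges, age[idx], side="right") - 1,
                       0, n_bands - 1)
        lam_f = np.where(fractured[idx], 0.0,
                         base_f[sex_code[idx], band] * rr_f[idx])
        lam_d = base_d[sex_code[idx], band] * rr_d[idx]
        lam = lam_f + lam_d + config.dereg_hazard
        band_end = np.where(band == n_bands - 1, np.inf, edges[np.minimum(band + 1, n_bands)])
        res = band_end - age[idx]
        rem = admin[idx] - t[idx]

        u = rng.random(idx.size)
        with np.errstate(divide="ignore"):
            e = np.where(lam > 0, -np.log1p(-u) / np.maximum(lam, 1e-300), np.inf)
        v = rng.random(idx.size)     # cause selector, drawn unconditionally

        is_event = e < np.minimum(res, rem)
        is_admin = ~is_event & (rem <= res)

        dt = np.minimum.reduce([e, res, rem])
        t[idx] += dt
        age[idx] += dt

        if is_event.any():
            ev = idx[is_event]
            lam_ev = lam[is_event]
            p_f = np.where(lam_ev > 0, lam_f[is_event] / lam_ev, 0.0)
            p_fd = np.where(lam_ev > 0, (lam_f[is_event] + lam_d[is_event]) / lam_ev, 0.0)
            vv = v[is_event]
            frac_hit = vv < p_f
            death_hit = ~frac_hit & (vv < p_fd)
            dereg_hit = ~frac_hit & ~death_hit
            frac_t[ev[frac_hit]] = t[ev[frac_hit]]
            fractured[ev[frac_hit]] = True
            death_t[ev[death_hit]] = t[ev[death_hit]]
            active[ev[death_hit]] = False
            dereg_t[ev[dereg_hit]] = t[ev[dereg_hit]]
            active[ev[dereg_hit]] = False
        active[idx[is_admin]] = False

    return frac_t, death_t, dereg_t


def _years_to_date(entry_date: pd.Series, years: np.ndarray) -> pd.Series:
    days = np.maximum(1, np.rint(years * DAYS_PER_YEAR)).astype(np.int64)
    return entry_date + pd.to_timedelta(days, unit="D")


def _materialise_events(config: HazardConfig, subjects: pd.DataFrame,
                        frac_t, death_t, dereg_t, rng) -> pd.DataFrame:
    rows = []
    entry_date = subjects["entry_date"]
    ids = subjects["id"].to_numpy()

    fmask = ~np.isnan(frac_t)
    if fmask.any():
        k = int(fmask.sum())
        kinds = _categorical_draw(
            rng, FRACTURE_KINDS,
            [config.fracture_kind_probs[x] for x in FRACTURE_KINDS], k)
        patterns = _categorical_draw(
            rng, SOURCE_PATTERNS,
            [config.source_probs[x] for x in SOURCE_PATTERNS], k)
        overlap = rng.random(k) < config.hospital_gp_overlap
        dates = _years_to_date(entry_date[fmask].reset_index(drop=True),
                               frac_t[fmask])
        fids = ids[fmask]
        for i in range(k):
            if patterns[i] == "gp_only":
                sources = ["gp"]
            elif patterns[i] == "hospital_involved":
                sources = ["hospital"] + (["gp"] if overlap[i] else [])
            else:
                sources = ["death_cert"]
            for src in sources:
                rows.append((fids[i], dates.iloc[i], kinds[i], src))

    dmask = ~np.isnan(death_t)
    if dmask.any():
        dates = _years_to_date(entry_date[dmask].reset_index(drop=True), death_t[dmask])
        for sid, date in zip(ids[dmask], dates):
            rows.append((sid, date, "nonfracture_death", "death_cert"))

    rmask = ~np.isnan(dereg_t)
    if rmask.any():
        dates = _years_to_date(entry_date[rmask].reset_index(drop=True), dereg_t[rmask])
        for sid, date in zip(ids[rmask], dates):
            rows.append((sid, date, "deregistration", "gp"))

    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    events["subject_id"] = events["subject_id"].astype(np.int64)
    events = events.sort_values(
        ["subject_id", "date", "kind", "sources"], kind="stable").reset_index(drop=True)
    return events


def simulate_cohort(config: HazardConfig, n: int, seed: int):
    """Simulate a linked cohort.

    Parameters
    ----------
    config : HazardConfig
        Validated generative configuration.
    n : int
        Number of subjects (>= 1).
    seed : int
        Root seed; identical (config, n, seed) give byte-identical output.

    Returns
    -------
    (subjects, events) : tuple of DataFrame
        ``subjects`` has one row per person (see FORMAT.md for the header
        contract); ``events`` has one row per dated, source-tagged record.
    """
    if n < 1:
        raise ConfigError("n: must be >= 1")
    config.validate()
    ss = np.random.SeedSequence(seed)
    rng_subj, rng_times, rng_events = (np.random.default_rng(s) for s in ss.spawn(3))
    subjects = _draw_subjects(config, n, rng_subj)
    frac_t, death_t, dereg_t = _simulate_event_times(config, subjects, rng_times)
    events = _materialise_events(config, subjects, frac_t, death_t, dereg_t, rng_events)
    return subjects, events


# --------------------------------------------------------------------------
# missingness


def apply_missingness(subjects: pd.DataFrame, rates: dict, mechanism: str = "MCAR",
                      seed: int = 0, mar_slope: float = 0.8) -> pd.DataFrame:
    """Blank covariate values to emulate routine-data missingness.

    ``mechanism`` is ``"MCAR"`` (uniform probability) or ``"MAR_on_age"``
    where the blanking probability is ``expit(alpha + mar_slope *
    (entry_age - 60)/10)`` with ``alpha`` calibrated so the marginal missing
    fraction matches the requested rate on this cohort.
    """
    for field, rate in rates.items():
        if field not in MASKABLE_FIELDS:
            raise ConfigError(f"missingness rate for non-maskable field {field!r}")
        if not 0 <= rate <= 1:
            raise ConfigError(f"missingness rate for {field!r} must be in [0, 1]")
    if mechanism not in ("MCAR", "MAR_on_age"):
        raise ConfigError(f"unknown missingness mechanism {mechanism!r}")

    out = subjects.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(out)
    age_term = (out["entry_age"].to_numpy(dtype=float) - 60.0) / 10.0

    for field in MASKABLE_FIELDS:       # fixed order for reproducibility
        if field not in rates or rates[field] == 0:
            continue
        rate = rates[field]
        if mechanism == "MCAR" or rate == 1:
            p = np.full(n, rate)
        else:
            lo, hi = np.min(mar_slope * age_term), np.max(mar_slope * age_term)
            alpha = brentq(
                lambda a: expit(a + mar_slope * age_term).mean() - rate,
                -40 - hi, 40 - lo)
            p = expit(alpha + mar_slope * age_term)
        mask = rng.random(n) < p
        if field == "bmi":
            out.loc[mask, field] = np.nan
        else:
            out[field] = out[field].astype(object)
            out.loc[mask, field] = None
    return out


# --------------------------------------------------------------------------
# true (model) risks implied by the generative hazards


def _band_segments(config: HazardConfig, entry_age: np.ndarray, horizon: float):
    """Yield (band index, per-subject duration) covering [entry, entry+horizon].

    The last band extends beyond its upper edge so follow-up past age 100
    keeps the final band's hazards.
    """
    edges = np.asarray(config.age_band_edges, dtype=float)
    n_bands = edges.size - 1
    end_age = entry_age + horizon
    for k in range(n_bands):
        lo = np.maximum(entry_age, edges[k])
        hi_edge = np.inf if k == n_bands - 1 else edges[k + 1]
        hi = np.minimum(end_age, hi_edge)
        dur = np.maximum(0.0, hi - lo)
        if np.any(dur > 0):
            yield k, dur


def _subject_band_hazards(config: HazardConfig, subjects: pd.DataFrame,
                          outcome: str = "major_osteoporotic"):
    from .levels import OUTCOME_KINDS
    base_f = np.stack([np.asarray(config.fracture_base_hazard[s], dtype=float)
                       for s in SEXES])
    base_d = np.stack([np.asarray(config.death_base_hazard[s], dtype=float)
                       for s in SEXES])
    if outcome not in OUTCOME_KINDS:
        raise ConfigError(f"unknown outcome {outcome!r}")
    kind_frac = sum(config.fracture_kind_probs[k] for k in OUTCOME_KINDS[outcome])
    sex_code = _sex_codes(subjects["sex"].to_numpy())
    lp_f, lp_d = _linear_predictors(config, subjects)
    return base_f, base_d, sex_code, np.exp(lp_f), np.exp(lp_d), kind_frac


def cumulative_fracture_hazard(config: HazardConfig, subjects: pd.DataFrame,
                               horizon: float = 10.0,
                               outcome: str = "major_osteoporotic") -> np.ndarray:
    """Per-subject cumulative cause-specific fracture hazard over ``horizon``."""
    base_f, _, sex_code, rr_f, _, kind_frac = _subject_band_hazards(
        config, subjects, outcome)
    entry_age = subjects["entry_age"].to_numpy(dtype=float)
    total = np.zeros(len(subjects))
    for k, dur in _band_segments(config, entry_age, horizon):
        total += base_f[sex_code, k] * rr_f * dur
    return kind_frac * total


def true_fracture_cif(config: HazardConfig, subjects: pd.DataFrame,
                      horizon: float = 10.0,
                      outcome: str = "major_osteoporotic") -> np.ndarray:
    """Per-subject true cumulative incidence of fracture by ``horizon``.

    Accounts for the competing death hazard (deregistration and
    administrative censoring are treated as independent censoring and do not
    enter the risk).  Under the generative model a first fracture is of the
    requested composite with fixed probability, so the composite CIF scales
    the all-fracture CIF by that kind fraction.
    """
    base_f, base_d, sex_code, rr_f, rr_d, kind_frac = _subject_band_hazards(
        config, subjects, outcome)
    entry_age = subjects["entry_age"].to_numpy(dtype=float)
    n = len(subjects)
    cif = np.zeros(n)
    cum = np.zeros(n)
    for k, dur in _band_segments(config, entry_age, horizon):
        lam_f = base_f[sex_code, k] * rr_f
        lam_d = base_d[sex_code, k] * rr_d
        lam = lam_f + lam_d
        with np.errstate(invalid="ignore", divide="ignore"):
            inc = np.where(lam > 0,
                           np.exp(-cum) * lam_f / np.maximum(lam, 1e-300)
                           * -np.expm1(-lam * dur),
                           0.0)
        cif += inc
        cum += lam * dur
    return kind_frac * cif


# --------------------------------------------------------------------------
# cohort IO


def write_cohort(subjects: pd.DataFrame, events: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = subjects.copy()
    s["entry_date"] = pd.to_datetime(s["entry_date"]).dt.strftime("%Y-%m-%d")
    s.to_csv(outdir / "subjects.csv", index=False, float_format="%.6f")
    e = events.copy()
    e["date"] = pd.to_datetime(e["date"]).dt.strftime("%Y-%m-%d")
    e.to_csv(outdir / "events.csv", index=False)


def read_cohort(indir):
    indir = Path(indir)
    subjects = pd.read_csv(indir / "subjects.csv", parse_dates=["entry_date"])
    for col in ("smoking", "alcohol", "ethnicity"):
        subjects[col] = subjects[col].astype(object).where(subjects[col].notna(), None)
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise DataError(f"subjects.csv: missing columns {missing}")
    events = pd.read_csv(indir / "events.csv", parse_dates=["date"])
    if list(events.columns) != list(EVENT_COLUMNS):
        raise DataError(f"events.csv: expected columns {EVENT_COLUMNS}")
    return subjects, events
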