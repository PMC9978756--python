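"""Pluggable Cox-form 10-year risk equations.

A risk equation is a linear predictor over transformed continuous terms,
categorical terms and binary flags, combined with a baseline 10-year survival
``S0``::

    risk = 1 - S0 ** exp(lp)

The transform spec for a continuous term supports fractional-polynomial style
forms in ``covariate / scale``: ``power == 0`` means ``ln(u)``, otherwise
``u ** power``, and the ``log`` flag multiplies by an extra ``ln(u)`` (the
repeated-power convention).  Each term is centred by subtracting a constant
from the transformed value, so a subject at reference/centred values has a
linear predictor of exactly zero.

The package deliberately ships only documented *toy* equations: the licensed
coefficients of published tools are not embedded, and the validation
machinery, not any coefficient set, is what this package provides.

Only values recorded before study entry appear in a Subject row, so
predictions automatically respect the pre-entry restriction.  Missing
ethnicity is scored as the reference level ("white"); any other missing
covariate the equation uses is an error (predict after imputation).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from numbers import Real

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .levels import BINARY_COVARIATES, CATEGORICAL_LEVELS, NUMERIC_COVARIATES

SCHEMA_VERSION = 1

OUTCOMES = ("major_osteoporotic", "hip")


@dataclasses.dataclass
class ContinuousTerm:
    covariate: str
    coefficient: float
    scale: float = 1.0
    power: float = 1.0
    log: bool = False
    center: float = 0.0

    def transform(self, x: np.ndarray) -> np.ndarray:
        u = np.asarray(x, dtype=float) / self.scale
        if np.any(u <= 0) and (self.power == 0 or self.log
                               or float(self.power) != int(self.power)):
            raise DataError(
                f"continuous term {self.covariate!r}: non-positive value "
                "under a log/fractional-power transform")
        v = np.log(u) if self.power == 0 else u ** self.power
        if self.log:
            v = v * np.log(u)
        return v

    def contribution(self, x: np.ndarray) -> np.ndarray:
        return self.coefficient * (self.transform(x) - self.center)


@dataclasses.dataclass
class RiskEquation:
    """A 10-year fracture risk equation in Cox form."""

    name: str
    outcome: str
    sex: str
    baseline_survival_10y: float
    continuous_terms: list          # of ContinuousTerm
    categorical_terms: dict         # covariate -> {level: coefficient}
    binary_terms: dict              # flag -> coefficient

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ConfigError(f"outcome: unknown outcome {self.outcome!r}")
        if self.sex not in ("female", "male"):
            raise ConfigError(f"sex: must be 'female' or 'male', got {self.sex!r}")
        s0 = self.baseline_survival_10y
        if not (isinstance(s0, Real) and 0 < s0 < 1):
            raise ConfigError(
                f"baseline_survival_10y: must be in (0, 1), got {s0!r}")
        for term in self.continuous_terms:
            if term.covariate not in NUMERIC_COVARIATES:
                raise ConfigError(
                    f"continuous_terms: unknown covariate {term.covariate!r}")
            if term.scale <= 0:
                raise ConfigError(
                    f"continuous_terms[{term.covariate}].scale: must be > 0")
        for cov, levels in self.categorical_terms.items():
            declared = CATEGORICAL_LEVELS.get(cov)
            if declared is None:
                raise ConfigError(
                    f"categorical_terms: unknown covariate {cov!r}")
            if set(levels) != set(declared):
                raise ConfigError(
                    f"categorical_terms[{cov}]: levels must match the declared "
                    f"level set {sorted(declared)}")
            if not any(float(c) == 0.0 for c in levels.values()):
                raise ConfigError(
                    f"categorical_terms[{cov}]: a reference level with "
                    "coefficient exactly 0 is required")
        for flag in self.binary_terms:
            if flag not in BINARY_COVARIATES:
                raise ConfigError(f"binary_terms: unknown flag {flag!r}")


def linear_predictor(eq: RiskEquation, subjects: pd.DataFrame) -> np.ndarray:
    """Evaluate the equation's linear predictor for each subject row.

    Raises a validation error naming the covariate and level on an unknown
    categorical level, and a data error on a missing covariate value other
    than ethnicity (scored as white).
    """
    lp = np.zeros(len(subjects))
    for term in eq.continuous_terms:
        x = subjects[term.covariate].to_numpy(dtype=float)
        if np.any(np.isnan(x)):
            raise DataError(
                f"missing values in continuous covariate {term.covariate!r}; "
                "impute before prediction")
        lp += term.contribution(x)
    for cov, coefs in eq.categorical_terms.items():
        vals = subjects[cov].to_numpy(dtype=object)
        if cov == "ethnicity":
            vals = np.where(pd.isna(vals), "white", vals)
        elif pd.isna(vals).any():
            raise DataError(
                f"missing values in categorical covariate {cov!r}; "
                "impute before prediction")
        unknown = set(vals) - set(coefs)
        if unknown:
            raise DataError(
                f"unknown level(s) {sorted(map(str, unknown))} for covariate {cov!r}")
        lp += np.array([coefs[v] for v in vals], dtype=float)
    for flag, coef in eq.binary_terms.items():
        lp += float(coef) * subjects[flag].to_numpy(dtype=float)
    return lp


def predict_risk_10y(eq: RiskEquation, subjects: pd.DataFrame) -> pd.DataFrame:
    """10-year predicted risk ``1 - S0**exp(lp)`` per subject.

    Returns a frame with columns ``subject_id``, ``linear_predictor``,
    ``risk_10y``.
    """
    lp = linear_predictor(eq, subjects)
    risk = 1.0 - eq.baseline_survival_10y ** np.exp(lp)
    return pd.DataFrame({
        "subject_id": subjects["id"].to_numpy(),
        "linear_predictor": lp,
        "risk_10y": risk,
    })


# --------------------------------------------------------------------------
# equation definition files


def load_equation(path) -> RiskEquation:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return equation_from_dict(raw)


def equation_from_dict(raw: dict) -> RiskEquation:
    if not isinstance(raw, dict):
        raise ConfigError("equation file: expected a mapping")
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version: expected {SCHEMA_VERSION}, got {version!r}")
    required = {"name", "outcome", "sex", "baseline_survival_10y"}
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"equation file: missing fields {sorted(missing)}")
    known = required | {"schema_version", "continuous_terms",
                        "categorical_terms", "binary_terms"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"equation file: unknown fields {sorted(unknown)}")
    cont = []
    for i, spec in enumerate(raw.get("continuous_terms") or []):
        extra = set(spec) - {"covariate", "coefficient", "scale", "power",
                             "log", "center"}
        if extra:
            raise ConfigError(
                f"continuous_terms[{i}]: unknown keys {sorted(extra)}")
        if "covariate" not in spec or "coefficient" not in spec:
            raise ConfigError(
                f"continuous_terms[{i}]: 'covariate' and 'coefficient' required")
        cont.append(ContinuousTerm(
            covariate=spec["covariate"],
            coefficient=float(spec["coefficient"]),
            scale=float(spec.get("scale", 1.0)),
            power=float(spec.get("power", 1.0)),
            log=bool(spec.get("log", False)),
            center=float(spec.get("center", 0.0)),
        ))
    eq = RiskEquation(
        name=str(raw["name"]),
        outcome=raw["outcome"],
        sex=raw["sex"],
        baseline_survival_10y=float(raw["baseline_survival_10y"]),
        continuous_terms=cont,
        categorical_terms={k: {lv: float(c) for lv, c in v.items()}
                           for k, v in (raw.get("categorical_terms") or {}).items()},
        binary_terms={k: float(v) for k, v in (raw.get("binary_terms") or {}).items()},
    )
    eq.validate()
    return eq


def save_equation(eq: RiskEquation, path) -> None:
    eq.validate()
    d = {
        "schema_version": SCHEMA_VERSION,
        "name": eq.name,
        "outcome": eq.outcome,
        "sex": eq.sex,
        "baseline_survival_10y": float(eq.baseline_survival_10y),
        "continuous_terms": [
            {"covariate": t.covariate, "coefficient": t.coefficient,
             "scale": t.scale, "power": t.power, "log": t.log,
             "center": t.center}
            for t in eq.continuous_terms],
        "categorical_terms": eq.categorical_terms,
        "binary_terms": eq.binary_terms,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def packaged_equation(outcome: str, sex: str) -> RiskEquation:
    """Load one of the shipped toy equations (per outcome and sex)."""
    name = f"{outcome}_{sex}"
    text = resources.files("fracval").joinpath(f"equations/{name}.yaml").read_text()
    return equation_from_dict(yaml.safe_load(text))


def packaged_equations() -> dict:
    """All four shipped toy equations keyed by (outcome, sex)."""
    return {(o, s): packaged_equation(o, s)
            for o in OUTCOMES for s in ("female", "male")}
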