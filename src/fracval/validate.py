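"""Whole-study validation runs: discrimination and calibration by subgroup.

Per (outcome, sex, subgroup) the run computes the truncated Harrell's C
(bootstrap CI), the Royston-Sauerbrei D with its explained-variation R2_D,
and a predicted-risk-decile calibration table under both the Kaplan-Meier
and Aalen-Johansen observed-risk estimators.  Metrics are computed per
imputed dataset and pooled: Rubin's rules for scalars (C on its own scale,
D with its model-based variance), decile-summary averaging for calibration
curves.  Deciles are formed within each analysis population, so every panel
has ten equally sized groups of its own subjects.

Subgroups: all patients; entry-age bands 30-64 / 65-74 / 75-84 / 85-99;
Charlson comorbidity groups 0 / 1 / 2 / 3+.  A subgroup with too few events
is flagged unavailable and the run continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .equation import packaged_equations, predict_risk_10y
from .errors import DataError
from .followup import charlson_index, determine_outcomes
from .impute import mice_impute, pool_rubin
from .metrics import (
    bootstrap_c_ci,
    calibration_deciles,
    harrell_c_truncated,
    r2_from_d,
    royston_d,
)

AGE_SUBGROUPS = {
    "30-64": (30.0, 65.0),
    "65-74": (65.0, 75.0),
    "75-84": (75.0, 85.0),
    "85-99": (85.0, 100.0),
}

CHARLSON_SUBGROUPS = ("0", "1", "2", "3+")

DISCRIMINATION_COLUMNS = (
    "outcome", "sex", "subgroup_type", "subgroup", "n", "events", "n_pairs",
    "harrell_c", "c_lo", "c_hi", "d_stat", "d_lo", "d_hi",
    "r2_d", "r2_lo", "r2_hi", "available",
)


@dataclasses.dataclass
class ValidationReport:
    discrimination: pd.DataFrame
    calibration: dict               # (outcome, sex, subgroup_type, subgroup) -> DataFrame
    manifest: dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (outcome, sex), block in self.discrimination.groupby(
                ["outcome", "sex"], sort=True):
            block.to_csv(outdir / f"discrimination_{outcome}_{sex}.csv",
                         index=False, float_format="%.6f")
        for (outcome, sex, gtype, group), table in sorted(self.calibration.items()):
            label = group.replace("+", "plus")
            table.to_csv(
                outdir / f"calibration_{outcome}_{sex}_{gtype}_{label}.csv",
                index=False, float_format="%.6f")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def _r2_interval(d_lo: float, d_hi: float):
    if np.isnan(d_lo) or np.isnan(d_hi):
        return np.nan, np.nan
    lo = 0.0 if d_lo <= 0.0 <= d_hi else min(r2_from_d(d_lo), r2_from_d(d_hi))
    return lo, max(r2_from_d(d_lo), r2_from_d(d_hi))


def _population_masks(subjects: pd.DataFrame, charlson: pd.Series, subgroups):
    entry_age = subjects["entry_age"].to_numpy(dtype=float)
    pops = []
    if "all" in subgroups:
        pops.append(("all", "all", np.ones(len(subjects), dtype=bool)))
    if "age" in subgroups:
        for label, (lo, hi) in AGE_SUBGROUPS.items():
            pops.append(("age", label, (entry_age >= lo) & (entry_age < hi)))
    if "charlson" in subgroups:
        groups = charlson.to_numpy(dtype=object)
        for label in CHARLSON_SUBGROUPS:
            pops.append(("charlson", label, groups == label))
    return pops


def run_validation(subjects: pd.DataFrame, events: pd.DataFrame,
                   equations: dict = None, *,
                   outcomes=("major_osteoporotic", "hip"),
                   horizon: float = 10.0,
                   m: int = 5, iterations: int = 5,
                   seed: int = 0,
                   subgroups=("all", "age", "charlson"),
                   restrict_sources=None,
                   n_boot: int = 200,
                   min_events: int = 10,
                   study_end=None) -> ValidationReport:
    """Run the full validation over outcomes, sexes and subgroups.

    ``equations`` maps (outcome, sex) to a RiskEquation; the shipped toy
    equations are used when omitted.  Deterministic given ``seed``.
    """
    if equations is None:
        equations = packaged_equations()
    charlson = charlson_index(subjects).set_index("subject_id")["group"]
    charlson = charlson.reindex(subjects["id"]).reset_index(drop=True)

    followups = {o: determine_outcomes(subjects, events, o,
                                       restrict_sources=restrict_sources,
                                       study_end=study_end)
                 for o in outcomes}
    first = followups[outcomes[0]]
    event_indicator = (first["cause"] == "fracture").astype(float).to_numpy()

    has_missing = any(subjects[v].isna().any() for v in ("bmi", "smoking", "alcohol"))
    if has_missing:
        imp = mice_impute(subjects, m=m, iterations=iterations, seed=seed,
                          event_indicator=event_indicator)
        datasets = imp.datasets
    else:
        datasets = [subjects]

    sex_arr = subjects["sex"].to_numpy(dtype=object)
    pops = _population_masks(subjects, charlson, subgroups)

    rows = []
    calibration = {}
    cell = 0
    for outcome in outcomes:
        fu = followups[outcome]
        times = fu["time"].to_numpy(dtype=float)
        causes = fu["cause"].to_numpy(dtype=object)
        risks_by_dataset = {}
        for sex in ("female", "male"):
            eq = equations[(outcome, sex)]
            risks_by_dataset[sex] = [
                predict_risk_10y(eq, ds)["risk_10y"].to_numpy() for ds in datasets]
        for sex in ("female", "male"):
            sex_mask = sex_arr == sex
            for gtype, glabel, gmask in pops:
                cell += 1
                mask = sex_mask & gmask
                idx = np.flatnonzero(mask)
                n_sub = idx.size
                n_events = int(np.sum(causes[idx] == "fracture"))
                row = {
                    "outcome": outcome, "sex": sex, "subgroup_type": gtype,
                    "subgroup": glabel, "n": n_sub, "events": n_events,
                    "n_pairs": 0, "harrell_c": np.nan, "c_lo": np.nan,
                    "c_hi": np.nan, "d_stat": np.nan, "d_lo": np.nan,
                    "d_hi": np.nan, "r2_d": np.nan, "r2_lo": np.nan,
                    "r2_hi": np.nan, "available": False,
                }
                risk_sets = [r[idx] for r in risks_by_dataset[sex]]
                degenerate = (n_sub < 10 or n_events < min_events
                              or all(np.ptp(r) == 0 for r in risk_sets))
                if not degenerate:
                    try:
                        cs, c_vars, ds_, d_vars = [], [], [], []
                        for j, r in enumerate(risk_sets):
                            c, n_pairs = harrell_c_truncated(
                                times[idx], causes[idx], r, horizon)
                            cs.append(c)
                            if n_boot > 0:
                                _, _, var = bootstrap_c_ci(
                                    times[idx], causes[idx], r, horizon,
                                    n_boot=n_boot,
                                    seed=(seed * 1000003 + cell * 101 + j) % 2**31)
                                c_vars.append(var)
                            d, se = royston_d(times[idx], causes[idx], r)
                            ds_.append(d)
                            d_vars.append(se ** 2)
                            if j == 0:
                                row["n_pairs"] = n_pairs
                        if len(cs) >= 2:
                            pc = pool_rubin(cs, c_vars if c_vars else [0.0] * len(cs))
                            pd_ = pool_rubin(ds_, d_vars)
                            row.update(harrell_c=pc.estimate, c_lo=pc.ci_low,
                                       c_hi=pc.ci_high, d_stat=pd_.estimate,
                                       d_lo=pd_.ci_low, d_hi=pd_.ci_high)
                        else:
                            c = cs[0]
                            d, d_se = ds_[0], np.sqrt(d_vars[0])
                            if n_boot > 0:
                                lo, hi, _ = bootstrap_c_ci(
                                    times[idx], causes[idx], risk_sets[0],
                                    horizon, n_boot=n_boot,
                                    seed=(seed * 1000003 + cell * 101) % 2**31)
                            else:
                                lo = hi = np.nan
                            row.update(harrell_c=c, c_lo=lo, c_hi=hi,
                                       d_stat=d, d_lo=d - 1.959964 * d_se,
                                       d_hi=d + 1.959964 * d_se)
                        row["r2_d"] = r2_from_d(row["d_stat"])
                        row["r2_lo"], row["r2_hi"] = _r2_interval(
                            row["d_lo"], row["d_hi"])
                        row["available"] = True
                    except DataError:
                        pass
                rows.append(row)
                if n_sub >= 10:
                    tables = [calibration_deciles(times[idx], causes[idx],
                                                  r, horizon, ids=idx)
                              for r in risk_sets]
                    pooled = tables[0].copy()
                    for col in ("mean_predicted", "observed_km", "observed_aj"):
                        pooled[col] = np.mean([t[col].to_numpy() for t in tables],
                                              axis=0)
                    calibration[(outcome, sex, gtype, glabel)] = pooled

    disc = pd.DataFrame(rows, columns=list(DISCRIMINATION_COLUMNS))
    manifest = {
        "seed": seed, "horizon": horizon, "m": len(datasets),
        "iterations": iterations, "n_boot": n_boot,
        "outcomes": list(outcomes), "subgroups": list(subgroups),
        "restrict_sources": sorted(restrict_sources) if restrict_sources else None,
        "n_subjects": int(len(subjects)),
        "equations": {f"{o}_{s}": eq.name for (o, s), eq in equations.items()},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]
    return ValidationReport(discrimination=disc, calibration=calibration,
                            manifest=manifest)
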