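"""Study outcome and censoring rules: follow-up, person-time, comorbidity.

Cohort exit is the earliest of the first qualifying fracture record, death,
deregistration, or administrative censoring at the study end.  A fracture and
a death recorded on the same date resolve to fracture (death registration can
itself carry the fracture code).  An event recorded on the entry date itself
is assigned half a day of follow-up so times stay strictly positive.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_YEAR
from .errors import DataError
from .levels import (
    CHARLSON_WEIGHTS,
    EVENT_KINDS,
    OUTCOME_KINDS,
    SOURCES,
)

logger = logging.getLogger(__name__)

HALF_DAY_YEARS = 0.5 / DAYS_PER_YEAR

FOLLOWUP_COLUMNS = ("subject_id", "time", "cause", "fracture_kind")


def determine_outcomes(subjects: pd.DataFrame, events: pd.DataFrame,
                       outcome: str = "major_osteoporotic",
                       restrict_sources=None,
                       study_end=None) -> pd.DataFrame:
    """Apply outcome and censoring rules, one follow-up row per subject.

    Parameters
    ----------
    outcome : {"major_osteoporotic", "hip"}
        Which fracture composite counts as the event.
    restrict_sources : iterable of {"gp", "hospital", "death_cert"}, optional
        Keep a fracture record only if at least one of its recording sources
        is in this set (ascertainment-restriction experiments).  ``None``
        keeps all sources.
    study_end : date-like, optional
        Administrative censoring date.  Defaults to the latest event date or
        entry date in the data (use the generating config's window end for
        simulated cohorts).

    Returns
    -------
    DataFrame with columns ``subject_id``, ``time`` (years, > 0), ``cause``
    ({"fracture", "death", "censored"}) and ``fracture_kind``.
    """
    if outcome not in OUTCOME_KINDS:
        raise DataError(f"unknown outcome {outcome!r}")
    if restrict_sources is not None:
        restrict = frozenset(restrict_sources)
        if not restrict:
            raise DataError("restrict_sources: must be non-empty when given")
        bad = restrict - set(SOURCES)
        if bad:
            raise DataError(f"restrict_sources: unknown sources {sorted(bad)}")
    else:
        restrict = None

    bad_kinds = set(events["kind"].unique()) - set(EVENT_KINDS)
    if bad_kinds:
        raise DataError(f"events: unknown kinds {sorted(bad_kinds)}")

    entry = subjects.set_index("id")["entry_date"]
    ev = events.merge(entry.rename("entry_date"), left_on="subject_id",
                      right_index=True, how="left")
    if ev["entry_date"].isna().any():
        orphans = ev.loc[ev["entry_date"].isna(), "subject_id"].unique()
        raise DataError(f"events reference unknown subjects {orphans[:5].tolist()}")
    days = (ev["date"] - ev["entry_date"]).dt.days.to_numpy()
    if np.any(days < 0):
        raise DataError("events: event predates subject entry")
    ev = ev.assign(time=np.maximum(days / DAYS_PER_YEAR, HALF_DAY_YEARS))

    if study_end is None:
        study_end = max(ev["date"].max() if len(ev) else subjects["entry_date"].max(),
                        subjects["entry_date"].max())
    admin_days = (pd.Timestamp(study_end) - subjects["entry_date"]).dt.days.to_numpy()
    if np.any(admin_days < 0):
        raise DataError("study_end predates some subjects' entry")
    admin_time = np.maximum(admin_days / DAYS_PER_YEAR, HALF_DAY_YEARS)

    is_frac = ev["kind"].isin(OUTCOME_KINDS[outcome])
    if restrict is not None:
        src_ok = ev["sources"].map(
            lambda s: bool(set(str(s).split("|")) & restrict))
        is_frac &= src_ok
    frac = (ev.loc[is_frac]
            .sort_values(["subject_id", "time", "kind"], kind="stable")
            .drop_duplicates("subject_id"))
    frac_time = frac.set_index("subject_id")["time"]
    frac_kind = frac.set_index("subject_id")["kind"]

    death = (ev.loc[ev["kind"] == "nonfracture_death"]
             .groupby("subject_id")["time"].min())
    dereg = (ev.loc[ev["kind"] == "deregistration"]
             .groupby("subject_id")["time"].min())

    ids = subjects["id"].to_numpy()
    t_frac = frac_time.reindex(ids).to_numpy(dtype=float)
    t_death = death.reindex(ids).to_numpy(dtype=float)
    t_dereg = dereg.reindex(ids).to_numpy(dtype=float)
    t_censor = np.fmin(np.where(np.isnan(t_dereg), np.inf, t_dereg), admin_time)

    # earliest of fracture / death / censoring; ties resolve fracture first,
    # then death over censoring
    t_frac_ = np.where(np.isnan(t_frac), np.inf, t_frac)
    t_death_ = np.where(np.isnan(t_death), np.inf, t_death)
    cause = np.where(t_frac_ <= np.minimum(t_death_, t_censor), "fracture",
                     np.where(t_death_ <= t_censor, "death", "censored"))
    time = np.where(cause == "fracture", t_frac_,
                    np.where(cause == "death", t_death_, t_censor))
    kind = np.where(cause == "fracture",
                    frac_kind.reindex(ids).to_numpy(dtype=object), None)

    return pd.DataFrame({
        "subject_id": ids,
        "time": time,
        "cause": cause,
        "fracture_kind": kind,
    }, columns=list(FOLLOWUP_COLUMNS))


def crude_incidence(followups: pd.DataFrame, subjects: pd.DataFrame = None,
                    age_band_edges=None, by_sex: bool = True,
                    cause: str = "fracture") -> pd.DataFrame:
    """Events and person-years per stratum, with rates per 1000 person-years.

    Strata are sex and/or entry-age band (both optional).  Person-years count
    each subject's full follow-up regardless of cause, so rates for different
    causes computed on the same follow-ups share denominators.  Strata with
    zero person-years are dropped with a warning.
    """
    if len(followups) == 0:
        raise DataError("followups: empty input")
    df = followups.copy()
    keys = []
    if by_sex or age_band_edges is not None:
        if subjects is None:
            raise DataError("subjects required for sex/age stratification")
        meta = subjects.set_index("id")[["sex", "entry_age"]]
        df = df.merge(meta, left_on="subject_id", right_index=True, how="left")
    if by_sex:
        keys.append("sex")
    if age_band_edges is not None:
        edges = np.asarray(age_band_edges, dtype=float)
        labels = [f"{int(lo)}-{int(hi) - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
        df["age_band"] = pd.cut(df["entry_age"], edges, right=False, labels=labels)
        keys.append("age_band")

    df["is_event"] = (df["cause"] == cause).astype(int)
    if keys:
        grouped = df.groupby(keys, observed=False).agg(
            events=("is_event", "sum"), person_years=("time", "sum"))
        rows = grouped.reset_index()
    else:
        rows = pd.DataFrame({"events": [df["is_event"].sum()],
                             "person_years": [df["time"].sum()]})
    zero = rows["person_years"] <= 0
    if zero.any():
        logger.warning("dropping %d strata with zero person-years", int(zero.sum()))
        rows = rows.loc[~zero].reset_index(drop=True)
    rows["rate_per_1000py"] = 1000.0 * rows["events"] / rows["person_years"]
    return rows


def charlson_index(subjects: pd.DataFrame) -> pd.DataFrame:
    """Charlson comorbidity score per subject (original 1/2/3/6 weights).

    Absent condition flags count as false.  Returns ``subject_id``,
    ``score`` and the analysis ``group`` ("0", "1", "2", "3+", the score
    truncated at 3).
    """
    score = np.zeros(len(subjects), dtype=int)
    for cond, weight in CHARLSON_WEIGHTS.items():
        if cond in subjects.columns:
            score += weight * subjects[cond].fillna(0).to_numpy(dtype=int)
    group = np.where(score >= 3, "3+", score.astype(str))
    return pd.DataFrame({
        "subject_id": subjects["id"].to_numpy(),
        "score": score,
        "group": group,
    })


def write_followups(followups: pd.DataFrame, path) -> None:
    out = followups.copy()
    out["time"] = out["time"].map(lambda t: f"{t:.6f}")
    out.to_csv(Path(path), index=False)


def read_followups(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    df["fracture_kind"] = df["fracture_kind"].astype(object).where(
        df["fracture_kind"].notna(), None)
    return df
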