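"""Outcome determination, censoring rules, incidence and Charlson scoring."""

import numpy as np
import pandas as pd
import pytest

import fracval as fv
from fracval.errors import DataError

from conftest import make_subjects


def make_events(rows):
    df = pd.DataFrame(rows, columns=["subject_id", "date", "kind", "sources"])
    df["date"] = pd.to_datetime(df["date"])
    return df


STUDY_END = pd.Timestamp("2016-03-31")


class TestDetermineOutcomes:
    def test_first_event_wins(self, subject_factory):
        s = subject_factory([{}])
        e = make_events([
            (0, "2006-07-02", "hip", "gp"),            # +1.5 y
            (0, "2008-01-01", "nonfracture_death", "death_cert"),
        ])
        fu = fv.determine_outcomes(s, e, "major_osteoporotic", study_end=STUDY_END)
        assert fu.loc[0, "cause"] == "fracture"
        assert fu.loc[0, "fracture_kind"] == "hip"
        assert fu.loc[0, "time"] == pytest.approx(1.5, abs=0.01)

    def test_duplicate_records_of_one_fracture_collapse(self, subject_factory):
        s = subject_factory([{}])
        e = make_events([
            (0, "2007-01-01", "distal_forearm", "gp"),
            (0, "2007-01-01", "distal_forearm", "hospital"),
        ])
        fu = fv.determine_outcomes(s, e, study_end=STUDY_END)
        assert len(fu) == 1
        assert fu.loc[0, "cause"] == "fracture"
        assert fu.loc[0, "time"] == pytest.approx(2.0, abs=0.01)

    def test_source_restriction_excludes_hospital_only_record(self, subject_factory):
        s = subject_factory([{}])
        e = make_events([
            (0, "2007-01-01", "hip", "hospital"),
            (0, "2009-01-01", "nonfracture_death", "death_cert"),
        ])
        fu = fv.determine_outcomes(s, e, restrict_sources=("gp", "death_cert"),
                                   study_end=STUDY_END)
        assert fu.loc[0, "cause"] == "death"
        assert fu.loc[0, "time"] == pytest.approx(4.0, abs=0.01)

    def test_same_day_fracture_and_death_resolves_to_fracture(self, subject_factory):
        s = subject_factory([{}])
        e = make_events([
            (0, "2010-06-01", "hip", "death_cert"),
            (0, "2010-06-01", "nonfracture_death", "death_cert"),
        ])
        fu = fv.determine_outcomes(s, e, study_end=STUDY_END)
        assert fu.loc[0, "cause"] == "fracture"

    def test_hip_outcome_ignores_other_fracture_kinds(self, subject_factory):
        s = subject_factory([{}])
        e = make_events([(0, "2007-01-01", "vertebral", "gp")])
        fu = fv.determine_outcomes(s, e, outcome="hip", study_end=STUDY_END)
        assert fu.loc[0, "cause"] == "censored"

    def test_no_events_censored_at_study_end(self, subject_factory):
        s = subject_factory([{}])
        fu = fv.determine_outcomes(s, make_events([]), study_end=STUDY_END)
        assert fu.loc[0, "cause"] == "censored"
        assert fu.loc[0, "time"] == pytest.approx(11.25, abs=0.02)

    def test_event_before_entry_rejected(self, subject_factory):
        s = subject_factory([{}])
        e = make_events([(0, "2004-01-01", "hip", "gp")])
        with pytest.raises(DataError, match="predates"):
            fv.determine_outcomes(s, e, study_end=STUDY_END)

    def test_deterministic_and_idempotent(self, default_cfg, cohort20k):
        subjects, events = cohort20k
        a = fv.determine_outcomes(subjects, events, study_end=default_cfg.study_end)
        b = fv.determine_outcomes(subjects, events, study_end=default_cfg.study_end)
        pd.testing.assert_frame_equal(a, b)

    def test_source_restriction_monotone(self, default_cfg, cohort20k):
        """Shrinking the allowed recording sources never increases the
        fracture count."""
        subjects, events = cohort20k
        counts = []
        for restrict in (None, ("gp", "hospital", "death_cert"),
                         ("gp", "death_cert"), ("gp",)):
            fu = fv.determine_outcomes(subjects, events,
                                       restrict_sources=restrict,
                                       study_end=default_cfg.study_end)
            counts.append((fu["cause"] == "fracture").sum())
        assert counts[0] == counts[1]
        assert counts[1] >= counts[2] >= counts[3]
        assert counts[2] > counts[3]       # death-cert records do exist

    def test_person_time_invariant_to_composite_without_fractures(self, default_cfg):
        import copy
        cfg = copy.deepcopy(default_cfg)
        for sex in ("female", "male"):
            cfg.fracture_base_hazard[sex] = [0.0] * cfg.n_bands()
        subjects, events = fv.simulate_cohort(cfg, 5000, seed=21)
        py = [fv.determine_outcomes(subjects, events, o,
                                    study_end=cfg.study_end)["time"].sum()
              for o in ("major_osteoporotic", "hip")]
        assert py[0] == py[1]


class TestCrudeIncidence:
    def test_rate_arithmetic(self):
        fu = pd.DataFrame({
            "subject_id": range(250),
            "time": [10.0] * 250,
            "cause": ["fracture"] * 10 + ["censored"] * 240,
            "fracture_kind": ["hip"] * 10 + [None] * 240,
        })
        rows = fv.crude_incidence(fu, by_sex=False)
        assert rows.loc[0, "person_years"] == 2500.0
        assert rows.loc[0, "rate_per_1000py"] == pytest.approx(4.0)

    def test_single_censored_subject_rate_zero(self):
        fu = pd.DataFrame({"subject_id": [0], "time": [10.0],
                           "cause": ["censored"], "fracture_kind": [None]})
        rows = fv.crude_incidence(fu, by_sex=False)
        assert rows.loc[0, "rate_per_1000py"] == 0.0

    def test_women_fracture_rate_exceeds_men(self, cohort20k, followups20k):
        subjects, _ = cohort20k
        rows = fv.crude_incidence(followups20k, subjects).set_index("sex")
        assert rows.loc["female", "rate_per_1000py"] > rows.loc["male", "rate_per_1000py"]

    def test_empty_followups_rejected(self):
        empty = pd.DataFrame(columns=["subject_id", "time", "cause", "fracture_kind"])
        with pytest.raises(DataError, match="empty"):
            fv.crude_incidence(empty, by_sex=False)


class TestCharlson:
    @pytest.mark.parametrize("flags, score, group", [
        ({}, 0, "0"),
        ({"diabetes": 1, "copd": 1}, 2, "2"),
        ({"metastatic_solid_tumour": 1}, 6, "3+"),
        ({"renal_disease": 1}, 2, "2"),
        ({"moderate_severe_liver_disease": 1, "dementia": 1}, 4, "3+"),
    ])
    def test_weighted_scores(self, subject_factory, flags, score, group):
        s = subject_factory([flags])
        out = fv.charlson_index(s)
        assert out.loc[0, "score"] == score
        assert out.loc[0, "group"] == group

    def test_absent_flag_columns_count_as_false(self):
        s = pd.DataFrame({"id": [0], "diabetes": [1]})
        out = fv.charlson_index(s)
        assert out.loc[0, "score"] == 1
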