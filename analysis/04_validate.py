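#!/usr/bin/env python
"""Discrimination and calibration by sex, age band and comorbidity.

Runs the full validation (truncated Harrell's C with bootstrap CI,
Royston-Sauerbrei D and R2_D, predicted-risk-decile calibration under both
the Kaplan-Meier and Aalen-Johansen observed-risk estimators), computed per
imputed dataset and pooled.  The characteristic pattern: discrimination is
far better in the whole population than within any age band, because age
dominates the risk gradient.
"""

from pathlib import Path

import pandas as pd

import fracval as fv

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 99


def main():
    cfg = fv.default_config()
    subjects, events = fv.read_cohort(ROOT / "cohort")
    report = fv.run_validation(subjects, events, m=5, iterations=5,
                               seed=SEED, n_boot=100,
                               study_end=cfg.study_end)
    report.save(ROOT / "validation")

    d = report.discrimination
    show = d[(d["outcome"] == "major_osteoporotic")
             & d["subgroup_type"].isin(["all", "age"]) & d["available"]]
    print(show[["sex", "subgroup", "harrell_c", "d_stat", "r2_d"]]
          .round(3).to_string(index=False))
    below = total = 0
    for (outcome, sex), block in d[d["available"]].groupby(["outcome", "sex"]):
        whole = block.loc[block["subgroup_type"] == "all", "harrell_c"].iloc[0]
        bands = block.loc[block["subgroup_type"] == "age", "harrell_c"]
        below += int((bands < whole).sum())
        total += len(bands)
    print(f"\n{below}/{total} age-band C estimates fall below their panel's "
          "whole-population C (age carries most of the discrimination; "
          "exceptions come from sparse-event bands)")
    print(f"report -> {ROOT / 'validation'}")


if __name__ == "__main__":
    main()
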