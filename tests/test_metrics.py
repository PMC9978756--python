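"""Discrimination and calibration metrics: concordance conventions, the
D-statistic construction and decile calibration invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fracval as fv
from fracval.errors import DataError
from fracval.metrics import KAPPA


def c_oracle(times, causes, risks, horizon=10.0):
    """O(n^2) pair enumeration: the definitional truncated concordance."""
    score, pairs = 0.0, 0
    n = len(times)
    for i in range(n):
        if causes[i] != "fracture" or times[i] > horizon:
            continue
        for j in range(n):
            if times[j] > times[i]:
                pairs += 1
                if risks[i] > risks[j]:
                    score += 1.0
                elif risks[i] == risks[j]:
                    score += 0.5
    return score, pairs


class TestHarrellC:
    def test_perfect_discrimination(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.full(4, "fracture", dtype=object)
        risks = np.array([0.9, 0.7, 0.5, 0.3])      # earlier event, higher risk
        cval, n_pairs = fv.harrell_c_truncated(t, c, risks)
        assert cval == 1.0 and n_pairs == 6

    def test_all_risks_tied_gives_half(self):
        t = np.array([1.0, 2.0, 3.0])
        c = np.full(3, "fracture", dtype=object)
        cval, _ = fv.harrell_c_truncated(t, c, np.zeros(3))
        assert cval == 0.5

    def test_tied_event_times_not_comparable(self):
        t = np.array([1.0, 1.0, 2.0])
        c = np.full(3, "fracture", dtype=object)
        _, n_pairs = fv.harrell_c_truncated(t, c, np.array([0.3, 0.2, 0.1]))
        assert n_pairs == 2

    def test_truncation_excludes_late_events(self):
        t = np.array([1.0, 12.0, 15.0])
        c = np.full(3, "fracture", dtype=object)
        _, n_pairs = fv.harrell_c_truncated(t, c, np.array([0.3, 0.2, 0.1]),
                                            horizon=10.0)
        assert n_pairs == 2      # only the t=1 event contributes pairs

    def test_agrees_with_untruncated_when_all_times_within_horizon(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(0.1, 9.0, size=300)
        c = rng.choice(["fracture", "death", "censored"], size=300).astype(object)
        r = rng.random(300)
        a = fv.harrell_c_truncated(t, c, r, horizon=10.0)
        b = fv.harrell_c_truncated(t, c, r, horizon=1e9)
        assert a == b

    def test_invariant_under_monotone_risk_transform(self):
        rng = np.random.default_rng(6)
        t = rng.uniform(0.1, 12.0, size=400)
        c = rng.choice(["fracture", "death", "censored"], size=400).astype(object)
        r = rng.random(400)
        a = fv.harrell_c_truncated(t, c, r)
        b = fv.harrell_c_truncated(t, c, np.exp(3 * r) - 1)
        assert a == b

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        t = rng.integers(1, 25, size=n) / 2.0
        c = rng.choice(["fracture", "death", "censored"], size=n).astype(object)
        r = rng.integers(0, 12, size=n) / 11.0
        cval, n_pairs = fv.harrell_c_truncated(t, c, r, horizon=8.0)
        s_o, p_o = c_oracle(t, c, r, horizon=8.0)
        assert n_pairs == p_o
        assert cval == s_o / p_o

    def test_no_comparable_pairs_rejected(self):
        t = np.array([1.0, 1.0])
        c = np.array(["censored", "censored"], dtype=object)
        with pytest.raises(DataError, match="comparable"):
            fv.harrell_c_truncated(t, c, np.array([0.1, 0.2]))


class TestRoystonD:
    def test_degenerate_equal_risks_rejected(self):
        t = np.array([1.0, 2.0, 3.0])
        c = np.full(3, "fracture", dtype=object)
        with pytest.raises(DataError, match="all equal"):
            fv.royston_d(t, c, np.ones(3))

    def test_doubling_prognostic_spread_doubles_d(self):
        rng = np.random.default_rng(7)
        n = 8000
        eta = rng.normal(size=n)
        d_vals = []
        for sigma in (0.5, 1.0):
            t = rng.exponential(1.0 / (0.05 * np.exp(sigma * eta)))
            c = np.full(n, "fracture", dtype=object)
            d, _ = fv.royston_d(t, c, sigma * eta)
            d_vals.append(d)
        assert d_vals[1] / d_vals[0] == pytest.approx(2.0, abs=0.2)


class TestR2FromD:
    def test_zero_and_analytic_kappa_point(self):
        assert fv.r2_from_d(0.0) == 0.0
        analytic = 100.0 / (1.0 + np.pi ** 2 / 6.0)
        assert fv.r2_from_d(KAPPA) == pytest.approx(analytic, abs=1e-10)

    def test_monotone_in_magnitude_and_sign_symmetric(self):
        grid = np.linspace(0, 5, 40)
        vals = [fv.r2_from_d(d) for d in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert fv.r2_from_d(-2.0) == fv.r2_from_d(2.0)

    def test_internal_identity_to_1e10(self):
        for d in (0.3, 1.1, 2.7):
            q = d ** 2 / (8 / np.pi)
            expected = 100 * q / (np.pi ** 2 / 6 + q)
            assert fv.r2_from_d(d) == pytest.approx(expected, abs=1e-10)


@pytest.fixture(scope="module")
def constant_hazard_risks():
    rng = np.random.default_rng(8)
    n = 50000
    rng.exponential(1 / 0.04, size=n)
    rng.random(n)
    return rng.normal(0.09, 0.001, size=n)      # near-constant predictions


@pytest.fixture(scope="module")
def constant_hazard_table(constant_hazard_risks):
    rng = np.random.default_rng(8)
    n = 50000
    t = rng.exponential(1 / 0.04, size=n)
    c = np.where(rng.random(n) < 0.25, "fracture", "death").astype(object)
    return fv.calibration_deciles(t, c, constant_hazard_risks, horizon=10.0)


class TestCalibrationDeciles:
    def test_decile_sizes_differ_by_at_most_one(self, constant_hazard_table):
        sizes = constant_hazard_table["n"]
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 50000

    def test_mean_predicted_non_decreasing(self, constant_hazard_table):
        assert constant_hazard_table["mean_predicted"].is_monotonic_increasing

    def test_km_exceeds_aj_under_competing_risk(self, constant_hazard_table):
        tab = constant_hazard_table
        assert (tab["observed_km"] >= tab["observed_aj"]).all()
        assert (tab["observed_km"] > tab["observed_aj"]).any()

    def test_constant_hazard_deciles_near_closed_forms(self, constant_hazard_table):
        """Every decile of an exchangeable population reproduces the
        closed-form net risk 1-exp(-0.1) (KM) and cause-1 CIF (AJ)."""
        tab = constant_hazard_table
        assert np.allclose(tab["observed_km"], 1 - np.exp(-0.1), atol=0.02)
        assert np.allclose(tab["observed_aj"], 0.25 * (1 - np.exp(-0.4)), atol=0.02)

    def test_predicted_mass_conserved(self, constant_hazard_table,
                                      constant_hazard_risks):
        tab = constant_hazard_table
        total = (tab["n"] * tab["mean_predicted"]).sum() / tab["n"].sum()
        assert total == pytest.approx(constant_hazard_risks.mean(), abs=1e-10)

    def test_too_few_subjects_rejected(self):
        t = np.array([1.0] * 5)
        c = np.full(5, "fracture", dtype=object)
        with pytest.raises(DataError, match="at least"):
            fv.calibration_deciles(t, c, np.arange(5.0))


def test_whole_population_c_exceeds_age_band_c(default_cfg):
    """With an age-dominated risk gradient, whole-population discrimination
    beats every within-age-band discrimination."""
    subjects, events = fv.simulate_cohort(default_cfg, 20000, seed=44)
    fu = fv.determine_outcomes(subjects, events, study_end=default_cfg.study_end)
    eq = fv.packaged_equation("major_osteoporotic", "female")
    risks = np.empty(len(subjects))
    for sex in ("female", "male"):
        eq = fv.packaged_equation("major_osteoporotic", sex)
        m = (subjects["sex"] == sex).to_numpy()
        risks[m] = fv.predict_risk_10y(eq, subjects[m])["risk_10y"].to_numpy()
    t = fu["time"].to_numpy()
    c = fu["cause"].to_numpy(dtype=object)
    age = subjects["entry_age"].to_numpy()
    c_all, _ = fv.harrell_c_truncated(t, c, risks)
    for lo, hi in ((30, 65), (65, 75), (75, 85), (85, 100)):
        m = (age >= lo) & (age < hi)
        if (c[m] == "fracture").sum() < 10:
            continue
        c_band, _ = fv.harrell_c_truncated(t[m], c[m], risks[m])
        assert c_all > c_band


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_c_bounded_and_transform_invariant(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    t = rng.integers(1, 10, size=n) / 2.0
    c = rng.choice(["fracture", "death", "censored"], size=n).astype(object)
    r = rng.random(n)
    try:
        cval, _ = fv.harrell_c_truncated(t, c, r)
    except DataError:
        return
    assert 0.0 <= cval <= 1.0
    cval2, _ = fv.harrell_c_truncated(t, c, 2 * r + 1)
    assert cval == cval2
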