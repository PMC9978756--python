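"""Kaplan-Meier, Aalen-Johansen and the Cox partial-likelihood fitter,
including cross-checks against lifelines and a grid-search oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fracval as fv
from fracval.errors import DataError

from conftest import competing_exponential


def random_mixed(seed, n=200):
    rng = np.random.default_rng(seed)
    t = rng.integers(1, 15, size=n) / 2.0          # forces ties
    c = rng.choice(["fracture", "death", "censored"], size=n).astype(object)
    return t, c


def test_km_hand_worked_product_limit():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    c = np.array(["fracture", "censored", "fracture", "censored"], dtype=object)
    km = fv.km_estimate(t, c)
    assert km.survival_at(3.0) == pytest.approx((1 - 1 / 4) * (1 - 1 / 2))
    assert km.survival_at(0.5) == 1.0


def test_km_no_target_events_gives_zero_risk():
    t = np.array([1.0, 2.0])
    c = np.array(["death", "censored"], dtype=object)
    km = fv.km_estimate(t, c)
    assert km.risk_at(10.0) == 0.0


def test_km_empty_input_rejected():
    with pytest.raises(DataError, match="empty"):
        fv.km_estimate(np.array([]), np.array([], dtype=object))


def test_aj_reduces_to_km_without_competing_cause():
    rng = np.random.default_rng(0)
    t = rng.exponential(5.0, size=500)
    c = np.where(rng.random(500) < 0.6, "fracture", "censored").astype(object)
    km = fv.km_estimate(t, c)
    aj = fv.aj_estimate(t, c)["fracture"]
    np.testing.assert_allclose(aj.cif, 1.0 - km.survival, atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_aj_additivity_and_km_dominance(seed):
    """Sum of cause CIFs plus all-cause survival is 1 at every jump, and the
    KM risk dominates the same-cause CIF pointwise."""
    t, c = random_mixed(seed)
    curves = fv.aj_estimate(t, c)
    frac, death = curves["fracture"], curves["death"]
    all_cause = fv.km_estimate(
        t, np.where(np.isin(c, ["fracture", "death"]), "fracture", "censored"))
    s_all = np.array([all_cause.survival_at(x) for x in frac.times])
    np.testing.assert_allclose(frac.cif + death.cif + s_all, 1.0, atol=1e-10)
    km = fv.km_estimate(t, c)
    for x in frac.times:
        assert km.risk_at(x) >= frac.value_at(x) - 1e-12


@pytest.mark.parametrize("seed", range(3))
def test_estimates_invariant_to_input_ordering(seed):
    t, c = random_mixed(seed)
    perm = np.random.default_rng(99).permutation(t.size)
    km1, km2 = fv.km_estimate(t, c), fv.km_estimate(t[perm], c[perm])
    np.testing.assert_array_equal(km1.times, km2.times)
    np.testing.assert_allclose(km1.survival, km2.survival, atol=1e-14)
    aj1 = fv.aj_estimate(t, c)["fracture"]
    aj2 = fv.aj_estimate(t[perm], c[perm])["fracture"]
    np.testing.assert_allclose(aj1.cif, aj2.cif, atol=1e-14)


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter
    t, c = random_mixed(17)
    km = fv.km_estimate(t, c)
    kmf = KaplanMeierFitter().fit(t, event_observed=(c == "fracture"))
    for x in km.times:
        assert km.survival_at(x) == pytest.approx(
            float(kmf.predict(x)), abs=1e-10)


class TestCox:
    def test_null_covariate_beta_near_zero(self):
        rng = np.random.default_rng(1)
        n = 4000
        t = rng.exponential(10.0, size=n)
        c = np.where(rng.random(n) < 0.5, "fracture", "censored").astype(object)
        x = rng.permutation(np.linspace(-1, 1, n))
        fit = fv.cox_fit_single(t, c, x)
        assert fit.converged
        assert abs(fit.beta) < 3 * fit.se

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        n = 10000
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
        c = np.full(n, "fracture", dtype=object)
        fit = fv.cox_fit_single(t, c, x)
        assert fit.beta == pytest.approx(0.7, abs=0.05)
        assert fit.se > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_grid_search_oracle(self, seed):
        """At n <= 30 the Newton solution's partial log-likelihood is no
        worse than a 10 001-point grid over [-5, 5]."""
        rng = np.random.default_rng(seed)
        n = 25
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        c = np.where(rng.random(n) < 0.7, "fracture", "censored").astype(object)
        if not (c == "fracture").any():
            c[0] = "fracture"
        fit = fv.cox_fit_single(t, c, x)
        grid = np.linspace(-5, 5, 10001)
        best = max(fv.cox_partial_loglik(t, c, x, b) for b in grid)
        assert fit.loglik >= best - 1e-9

    def test_matches_lifelines_on_tie_free_data(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(3)
        n = 800
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.4 * x))
        c = np.where(rng.random(n) < 0.8, "fracture", "censored").astype(object)
        fit = fv.cox_fit_single(t, c, x)
        df = pd.DataFrame({"t": t, "e": (c == "fracture").astype(int), "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert fit.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_no_events_rejected(self):
        t = np.array([1.0, 2.0])
        c = np.array(["censored", "censored"], dtype=object)
        with pytest.raises(DataError, match="no events"):
            fv.cox_fit_single(t, c, np.array([0.0, 1.0]))

    def test_constant_covariate_rejected(self):
        t = np.array([1.0, 2.0])
        c = np.array(["fracture", "fracture"], dtype=object)
        with pytest.raises(DataError, match="constant"):
            fv.cox_fit_single(t, c, np.array([1.0, 1.0]))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.tuples(st.integers(1, 12),
                          st.sampled_from(["fracture", "death", "censored"])),
                min_size=2, max_size=60))
def test_km_survival_monotone_and_bounded(data):
    t = np.array([d[0] for d in data], dtype=float)
    c = np.array([d[1] for d in data], dtype=object)
    km = fv.km_estimate(t, c)
    assert np.all(np.diff(km.survival) <= 1e-12)
    assert np.all((km.survival >= 0) & (km.survival <= 1))
    curves = fv.aj_estimate(t, c)
    for curve in curves.values():
        assert np.all(np.diff(curve.cif) >= -1e-12)
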