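"""Nonparametric survival estimators and a single-covariate Cox fitter.

Implements the product-limit (Kaplan-Meier) estimator, the Aalen-Johansen
cumulative incidence estimator with death as a competing event, and a
Newton-Raphson maximiser of the Cox partial likelihood with Breslow tie
handling.  These primitives carry the package's calibration and D-statistic
machinery, with conventions fixed here:

* at a tied time, events precede censorings (censored subjects at t remain
  in the risk set for events at t);
* a curve evaluated at horizon t takes the step-function value at the
  largest jump time <= t;
* the Aalen-Johansen curves satisfy sum_k CIF_k(t) + S_all(t) = 1 exactly at
  every jump, because the increments telescope against the all-cause
  product-limit estimate.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DataError, NumericError

CAUSES = ("fracture", "death", "censored")


def _validate_inputs(times, causes):
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=object)
    if times.size == 0:
        raise DataError("empty input")
    if times.shape != causes.shape:
        raise DataError("times and causes must have equal length")
    if np.any(times <= 0):
        raise DataError("times must be strictly positive")
    unknown = set(causes) - set(CAUSES)
    if unknown:
        raise DataError(f"unknown causes {sorted(map(str, unknown))}")
    return times, causes


def _step_value(times: np.ndarray, values: np.ndarray, t: float,
                before: float) -> float:
    """Right-continuous step lookup: value at the largest jump time <= t."""
    i = np.searchsorted(times, t, side="right")
    return before if i == 0 else float(values[i - 1])


@dataclasses.dataclass
class SurvivalCurve:
    """Product-limit survival estimate over distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        return _step_value(self.times, self.survival, t, before=1.0)

    def risk_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)


@dataclasses.dataclass
class CIFCurve:
    """Aalen-Johansen cumulative incidence for one cause."""

    cause: str
    times: np.ndarray
    cif: np.ndarray

    def value_at(self, t: float) -> float:
        return _step_value(self.times, self.cif, t, before=0.0)


def _counting_arrays(times, event_mask, any_event_mask=None):
    """Distinct event times with event counts and risk-set sizes."""
    order = np.argsort(times, kind="stable")
    ts = times[order]
    n = ts.size
    uniq, first = np.unique(ts, return_index=True)
    # subjects with time >= t are at risk at t (events before censorings)
    at_risk = n - first
    d = np.add.reduceat(event_mask[order].astype(float), first)
    return uniq, at_risk.astype(float), d


def km_estimate(times, causes, event_cause: str = "fracture") -> SurvivalCurve:
    """Kaplan-Meier estimate treating all non-target causes as censoring."""
    times, causes = _validate_inputs(times, causes)
    event = causes == event_cause
    uniq, at_risk, d = _counting_arrays(times, event)
    keep = d > 0
    uniq, at_risk, d = uniq[keep], at_risk[keep], d[keep]
    surv = np.cumprod(1.0 - d / at_risk)
    return SurvivalCurve(times=uniq, survival=surv, at_risk=at_risk, events=d)


def aj_estimate(times, causes, event_causes=("fracture", "death")) -> dict:
    """Aalen-Johansen cumulative incidence, one curve per competing cause.

    ``CIF_k(t) = sum_{t_i <= t} S_all(t_i-) d_{k,i} / n_i`` where ``S_all``
    is the all-cause event-free product-limit estimate.
    """
    times, causes = _validate_inputs(times, causes)
    any_event = np.isin(causes, event_causes)
    uniq, at_risk, d_all = _counting_arrays(times, any_event)
    keep = d_all > 0
    uniq, at_risk, d_all = uniq[keep], at_risk[keep], d_all[keep]
    s_all = np.cumprod(1.0 - d_all / at_risk)
    s_before = np.concatenate([[1.0], s_all[:-1]])

    order = np.argsort(times, kind="stable")
    ts = times[order]
    first = np.searchsorted(ts, uniq, side="left")
    curves = {}
    for cause in event_causes:
        mask = (causes == cause)[order].astype(float)
        csum = np.concatenate([[0.0], np.cumsum(mask)])
        nxt = np.searchsorted(ts, uniq, side="right")
        d_k = csum[nxt] - csum[first]
        cif = np.cumsum(s_before * d_k / at_risk)
        curves[cause] = CIFCurve(cause=cause, times=uniq, cif=cif)
    return curves


@dataclasses.dataclass
class CoxFit:
    beta: float
    se: float
    loglik: float
    iterations: int
    converged: bool


def cox_partial_loglik(times, causes, x, beta: float,
                       event_cause: str = "fracture") -> float:
    """Breslow partial log-likelihood at ``beta`` (x internally centred)."""
    times, causes = _validate_inputs(times, causes)
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    ll, _, _ = _cox_derivatives(times, causes == event_cause, xc, beta)
    return ll


def _cox_derivatives(times, event_mask, x, beta):
    order = np.argsort(times, kind="stable")
    ts, xs, ev = times[order], x[order], event_mask[order]
    w = np.exp(beta * xs)
    # suffix sums: risk set at t_i is everyone with time >= t_i
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xs)[::-1])[::-1]
    s2 = np.cumsum((w * xs * xs)[::-1])[::-1]
    first = np.searchsorted(ts, ts, side="left")
    fi = first[ev]
    m0, m1, m2 = s0[fi], s1[fi], s2[fi]
    ll = float(np.sum(beta * xs[ev] - np.log(m0)))
    score = float(np.sum(xs[ev] - m1 / m0))
    info = float(np.sum(m2 / m0 - (m1 / m0) ** 2))
    return ll, score, info


def cox_fit_single(times, causes, x, event_cause: str = "fracture",
                   tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Fit a one-covariate Cox model by Newton-Raphson (Breslow ties).

    Convergence when |score| < tol; the standard error comes from the
    inverse observed information.  The covariate is centred internally
    (beta and se are unaffected; the reported log-likelihood is that of
    the centred model).
    """
    times, causes = _validate_inputs(times, causes)
    x = np.asarray(x, dtype=float)
    event_mask = causes == event_cause
    if not event_mask.any():
        raise DataError(f"no events of cause {event_cause!r}")
    if np.ptp(x) == 0:
        raise DataError("covariate is constant")
    xc = x - x.mean()

    beta = 0.0
    ll, score, info = _cox_derivatives(times, event_mask, xc, beta)
    it = 0
    converged = abs(score) < tol
    while not converged and it < max_iter:
        it += 1
        step = score / info if info > 0 else 0.0
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_derivatives(times, event_mask, xc, new_beta)
        # step-halving keeps the likelihood non-decreasing
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_derivatives(
                times, event_mask, xc, new_beta)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        converged = abs(score) < tol
    if info <= 0:
        raise NumericError("non-positive observed information in Cox fit")
    return CoxFit(beta=float(beta), se=float(1.0 / np.sqrt(info)),
                  loglik=float(ll), iterations=it, converged=bool(converged))


def export_curve(curve, path) -> None:
    """Write a step-function table (time, estimate) as delimited text."""
    import pandas as pd
    if isinstance(curve, SurvivalCurve):
        df = pd.DataFrame({"time": curve.times, "estimate": curve.survival})
    else:
        df = pd.DataFrame({"time": curve.times, "estimate": curve.cif})
    df.to_csv(path, index=False, float_format="%.10f")
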