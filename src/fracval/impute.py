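"""Multiple imputation by chained equations, and Rubin's-rules pooling.

Three routinely incomplete covariates are imputed: BMI (continuous),
smoking and alcohol (categorical).  Conditional models:

* BMI: Bayesian linear regression with predictive mean matching (5 donors).
  Regression parameters are drawn from their posterior (normal-inverse-chi2
  with a flat prior) each sweep, so between-imputation variance is properly
  propagated into Rubin's rules.
* smoking, alcohol: multinomial logistic regression; the imputed level is
  drawn from the fitted conditional probabilities.  Parameter uncertainty of
  the multinomial model is not re-drawn (a documented approximation).

Default predictors are entry age, sex, prior fracture, the other two imputed
variables, and optionally an event indicator supplied by the caller.  The
sweep order is bmi, smoking, alcohol; observed values are never modified.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import ConfigError, DataError
from .levels import ALCOHOL_LEVELS, SMOKING_LEVELS

IMPUTABLE = ("bmi", "smoking", "alcohol")

_LEVELS = {"smoking": SMOKING_LEVELS, "alcohol": ALCOHOL_LEVELS}

PMM_DONORS = 5


@dataclasses.dataclass
class ImputationSet:
    """m completed copies of the subject table."""

    m: int
    datasets: list
    seed: int
    iterations: int


@dataclasses.dataclass
class PooledEstimate:
    """Rubin's-rules combination of m estimates.

    ``total_var = within_var + (1 + 1/m) * between_var``; the confidence
    interval uses the standard MI degrees of freedom
    ``(m - 1) * (1 + within / ((1 + 1/m) * between))^2`` (normal quantile
    when the between-imputation variance is zero).
    """

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    ci_low: float
    ci_high: float
    df: float


def _design_matrix(df: pd.DataFrame, exclude: str, extra: np.ndarray = None):
    cols = [np.ones(len(df))]
    cols.append(df["entry_age"].to_numpy(dtype=float))
    cols.append((df["sex"].to_numpy(dtype=object) == "male").astype(float))
    cols.append(df["prior_fracture"].to_numpy(dtype=float))
    if exclude != "bmi":
        cols.append(df["bmi"].to_numpy(dtype=float))
    for var in ("smoking", "alcohol"):
        if var == exclude:
            continue
        vals = df[var].to_numpy(dtype=object)
        for level in _LEVELS[var][1:]:      # reference level dropped
            cols.append((vals == level).astype(float))
    if extra is not None:
        cols.append(np.asarray(extra, dtype=float))
    return np.column_stack(cols)


def _pmm_draw(X_obs, y_obs, X_mis, rng):
    """Bayesian linear regression + predictive mean matching (5 donors)."""
    n, p = X_obs.shape
    beta_hat, _, _, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_draw = float(resid @ resid) / rng.chisquare(dof)
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    cov = sigma2_draw * xtx_inv
    beta_draw = rng.multivariate_normal(beta_hat, cov, method="svd")
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_draw
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    # candidate window of 2k neighbours around the insertion point, then the
    # k closest by predicted mean; clipping at the edges may duplicate
    # boundary donors, which only reweights the extremes slightly
    k = min(PMM_DONORS, n)
    offsets = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n - 1)
    cand_idx = order[cand]
    dist = np.abs(pred_obs[cand_idx] - pred_mis[:, None])
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    donor_rows = np.take_along_axis(cand_idx, nearest, axis=1)
    choice = rng.integers(0, k, size=pred_mis.size)
    picks = donor_rows[np.arange(pred_mis.size), choice]
    return y_obs[picks]


def _multinomial_draw(X_obs, y_obs, X_mis, levels, rng):
    present = [lv for lv in levels if lv in set(y_obs)]
    if len(present) == 1:
        return np.full(X_mis.shape[0], present[0], dtype=object)
    # standardise (sklearn adds its own intercept; drop ours) for a fast,
    # well-conditioned lbfgs fit; mild ridge regularisation is acceptable in
    # an imputation model
    mu = X_obs[:, 1:].mean(axis=0)
    sd = np.maximum(X_obs[:, 1:].std(axis=0), 1e-8)
    model = LogisticRegression(max_iter=500)
    model.fit((X_obs[:, 1:] - mu) / sd, y_obs.astype(str))
    probs = model.predict_proba((X_mis[:, 1:] - mu) / sd)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(X_mis.shape[0])
    idx = (u[:, None] > cum).sum(axis=1)
    return model.classes_[np.minimum(idx, len(model.classes_) - 1)].astype(object)


def mice_impute(subjects: pd.DataFrame, m: int = 5, iterations: int = 10,
                seed: int = 0, event_indicator=None) -> ImputationSet:
    """Chained-equations multiple imputation of bmi, smoking and alcohol.

    Deterministic given ``seed``; returns ``m`` completed datasets.  A
    variable that is 100% missing is an error (no donor information); a
    variable with no missing values is left untouched.
    """
    if m < 2:
        raise ConfigError("m: need at least 2 imputed datasets")
    if iterations < 1:
        raise ConfigError("iterations: must be >= 1")
    miss = {}
    for var in IMPUTABLE:
        mask = subjects[var].isna().to_numpy()
        if mask.all():
            raise DataError(f"variable {var!r} is 100% missing; cannot impute")
        if mask.any():
            miss[var] = mask
    extra = None
    if event_indicator is not None:
        extra = np.asarray(event_indicator, dtype=float)
        if extra.shape[0] != len(subjects):
            raise DataError("event_indicator must align with subjects")

    ss = np.random.SeedSequence(seed)
    datasets = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        df = subjects.copy()
        if not miss:
            datasets.append(df)
            continue
        # initial fill: random draws from the observed margins
        for var, mask in miss.items():
            observed = df.loc[~mask, var].to_numpy()
            df.loc[mask, var] = observed[rng.integers(0, observed.size,
                                                      size=int(mask.sum()))]
        for _ in range(iterations):
            for var in IMPUTABLE:
                if var not in miss:
                    continue
                mask = miss[var]
                X = _design_matrix(df, exclude=var, extra=extra)
                if var == "bmi":
                    y = subjects["bmi"].to_numpy(dtype=float)
                    df.loc[mask, "bmi"] = _pmm_draw(
                        X[~mask], y[~mask], X[mask], rng)
                else:
                    y = subjects[var].to_numpy(dtype=object)
                    df.loc[mask, var] = _multinomial_draw(
                        X[~mask], y[~mask], X[mask], _LEVELS[var], rng)
        datasets.append(df)
    return ImputationSet(m=m, datasets=datasets, seed=seed, iterations=iterations)


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine per-dataset estimates and variances by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise DataError("estimates and variances must be equal-length vectors")
    m = q.size
    if m < 2:
        raise DataError("need at least two imputations to pool")
    if np.any(u < 0):
        raise DataError("variances must be non-negative")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b > 0 and t > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        crit = stats.t.ppf(0.975, df)
    else:
        df = np.inf
        crit = stats.norm.ppf(0.975)
    half = crit * np.sqrt(t)
    return PooledEstimate(estimate=qbar, within_var=w, between_var=b,
                          total_var=t, ci_low=qbar - half, ci_high=qbar + half,
                          df=float(df))


def save_imputation_set(imp: ImputationSet, outdir) -> None:
    """Persist as m suffixed tables plus a manifest."""
    import json
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for j, df in enumerate(imp.datasets, start=1):
        out = df.copy()
        out["entry_date"] = pd.to_datetime(out["entry_date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(outdir / f"subjects_imp{j}.csv", index=False, float_format="%.6f")
    manifest = {"m": imp.m, "seed": imp.seed, "iterations": imp.iterations,
                "files": [f"subjects_imp{j}.csv" for j in range(1, imp.m + 1)]}
    (outdir / "imputation_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
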