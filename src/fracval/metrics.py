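"""Discrimination and calibration metrics for 10-year risk predictions.

Discrimination: Harrell's C truncated at the prediction horizon (only pairs
whose earliest survival time is within the horizon are compared, and
competing deaths act as censoring), the Royston-Sauerbrei D statistic
(separation in event-free survival across the prognostic-index distribution,
estimated by a Cox fit on scaled normal order statistics) and its companion
explained-variation statistic R2_D.

Calibration: deciles of predicted risk with observed risk estimated two
ways -- the Kaplan-Meier complement (ignores competing mortality, matching
how fracture equations are usually derived) and the Aalen-Johansen cumulative
incidence (accounts for it).  The gap between the two estimators in
high-mortality groups is the competing-risk over-prediction mechanism.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .errors import DataError
from .estimators import aj_estimate, cox_fit_single, km_estimate

#: kappa = sqrt(8/pi), the standard-normal mean absolute deviation factor
#: relating the D statistic to the prognostic-index spread.
KAPPA = float(np.sqrt(8.0 / np.pi))

#: Variance of the standard logistic-like error term on the log-hazard
#: scale used by the explained-variation transformation.
SIGMA2 = float(np.pi ** 2 / 6.0)


def harrell_c_truncated(times, causes, risks, horizon: float = 10.0):
    """Truncated Harrell's C.

    Comparable pairs (i, j) have ``t_i < t_j`` with subject i a fracture
    event and ``t_i <= horizon``.  A pair is concordant when the earlier
    event has the higher predicted risk; ties in risk score 0.5; pairs with
    tied event times are not comparable.

    Returns ``(c, n_pairs)``.
    """
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=object)
    risks = np.asarray(risks, dtype=float)
    if not (times.shape == causes.shape == risks.shape):
        raise DataError("times, causes and risks must align")
    if horizon <= 0:
        raise DataError("horizon must be > 0")
    event_idx = np.flatnonzero((causes == "fracture") & (times <= horizon))
    score = 0.0
    n_pairs = 0
    chunk = max(1, int(2 ** 22 // max(times.size, 1)))
    for lo in range(0, event_idx.size, chunk):
        ii = event_idx[lo:lo + chunk]
        later = times[None, :] > times[ii, None]
        conc = (risks[None, :] < risks[ii, None]) & later
        tied = (risks[None, :] == risks[ii, None]) & later
        score += float(conc.sum()) + 0.5 * float(tied.sum())
        n_pairs += int(later.sum())
    if n_pairs == 0:
        raise DataError("no comparable pairs within the horizon")
    return score / n_pairs, n_pairs


def bootstrap_c_ci(times, causes, risks, horizon: float = 10.0,
                   n_boot: int = 200, seed: int = 0):
    """Nonparametric bootstrap percentile CI (and variance) for truncated C."""
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=object)
    risks = np.asarray(risks, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = times.size
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            c, _ = harrell_c_truncated(times[idx], causes[idx], risks[idx], horizon)
        except DataError:
            continue
        reps.append(c)
    if len(reps) < 2:
        raise DataError("bootstrap produced fewer than two valid replicates")
    reps = np.asarray(reps)
    lo, hi = np.quantile(reps, [0.025, 0.975])
    return float(lo), float(hi), float(reps.var(ddof=1))


def royston_d(times, causes, risks, event_cause: str = "fracture"):
    """Royston-Sauerbrei D statistic and its standard error.

    Subjects are ranked by predicted risk; the ranks are mapped to expected
    standard-normal order statistics (Blom approximation), scaled by
    1/kappa with kappa = sqrt(8/pi), and the D statistic is the Cox
    coefficient on that constructed covariate.
    """
    risks = np.asarray(risks, dtype=float)
    if np.ptp(risks) == 0:
        raise DataError("risks are all equal; D statistic undefined")
    n = risks.size
    ranks = rankdata(risks)                       # average ranks on ties
    z = ndtri((ranks - 0.375) / (n + 0.25))       # Blom scores
    fit = cox_fit_single(times, causes, z / KAPPA, event_cause=event_cause)
    return fit.beta, fit.se


def r2_from_d(d_stat: float) -> float:
    """Explained variation (percent) from the D statistic.

    ``R2_D = 100 * (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2)`` with
    ``kappa^2 = 8/pi``.
    """
    q = d_stat ** 2 / KAPPA ** 2
    return 100.0 * q / (SIGMA2 + q)


def calibration_deciles(times, causes, risks, horizon: float = 10.0,
                        ids=None, n_groups: int = 10) -> pd.DataFrame:
    """Observed-vs-predicted calibration by predicted-risk decile.

    Deciles are formed by a stable sort on (risk, subject id), so ties break
    reproducibly; group sizes differ by at most one.  Per decile the table
    reports mean predicted risk, the Kaplan-Meier observed risk
    ``1 - S(horizon)`` and the Aalen-Johansen fracture CIF at the horizon.
    """
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=object)
    risks = np.asarray(risks, dtype=float)
    n = times.size
    if n < n_groups:
        raise DataError(f"need at least {n_groups} subjects for {n_groups} groups")
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids), risks))
    rows = []
    for g, grp in enumerate(np.array_split(order, n_groups), start=1):
        if grp.size == 0 or np.sum(times[grp]) <= 0:
            raise DataError(f"decile {g} has zero person-time")
        km = km_estimate(times[grp], causes[grp], event_cause="fracture")
        aj = aj_estimate(times[grp], causes[grp])["fracture"]
        rows.append({
            "decile": g,
            "n": int(grp.size),
            "mean_predicted": float(risks[grp].mean()),
            "observed_km": km.risk_at(horizon),
            "observed_aj": aj.value_at(horizon),
        })
    return pd.DataFrame(rows)
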