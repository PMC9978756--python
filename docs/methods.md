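# Methods

## Generative model for the synthetic cohort

Each subject carries a sex, a continuous entry age in [30, 100), a calendar
entry date, covariates (BMI; 6-level smoking and alcohol categories; 9-level
ethnicity; a prior-fracture flag; 17 Charlson condition flags plus a falls
flag, each with logistic age gradients), and experiences three competing
processes with piecewise-constant hazards over 10-year age bands:

* **fracture** — cause-specific hazard `λ_f(a) = base_f(band(a), sex) ·
  exp(lp_f)`, where `lp_f` sums configured log hazard ratios over binary
  covariates (default: prior fracture 0.55, rheumatologic disease 0.35,
  history of falls 0.40);
* **non-fracture death** — `λ_d(a) = base_d(band(a), sex) · exp(lp_d)`,
  with `lp_d = 0` by default (a separate map allows covariate effects on
  death): the deliberate asymmetry means the risk score never fully
  captures mortality, which is the over-prediction mechanism under study;
* **deregistration** — constant hazard (default 0.02/year; the rate of
  leaving a practice is not identifiable from published sources, so it is a
  free parameter chosen to yield a median follow-up of roughly 5-6 years
  together with administrative censoring).

Event times are sampled exactly: within each age band the subject traverses,
the total hazard is constant, so a competing exponential draw either lands
inside the band (the cause is then drawn proportionally to the cause-specific
hazards) or the subject advances to the next band boundary, the
administrative-censoring time, whichever comes first. Hazards of the last
band extend beyond age 100 for subjects who age past it during follow-up.
A subject has at most one true fracture, but the death/deregistration
processes keep running afterwards so that analyses which discard that
fracture record (source-restricted ascertainment) still observe the
subject's subsequent follow-up.

Entry dates are uniform over the study window (2004-01-01 to 2016-03-31)
with administrative censoring at the window end. Entry ages follow a scaled
Beta(1.4, 3.2) (mean ≈ 51 years, matching a primary-care age structure); the
demo configuration uses Beta(1, 1) so old age bands carry enough person-time
for per-band calibration.

**Default hazards.** Per-band rates (events/person-year) rise from ~0.0012
(ages 30-39) to 0.045 (women) / 0.020 (men) for fracture at ages 90-99,
while non-fracture death rises to 0.18 / 0.20 — giving the targeted
death/fracture incidence ratios of ≈4 (women) and ≈10 (men) in the oldest
band and crude composite-fracture incidence near 6 (women) and 2-3 (men) per
1000 person-years. These are qualitative stand-ins for published UK
incidence, not a calibration to any licensed dataset.

**Recording sources.** A fracture is recorded under one of three patterns:
`gp_only` (p = 0.72, a general-practice record), `hospital_involved`
(p = 0.25, a hospital-discharge record, accompanied by a same-dated GP
record with probability 0.4), or `death_certificate` (p = 0.03). The
resulting hospital-only capture fraction, 0.25 × 0.6 = 15%, mirrors the
share of fractures visible only in admission data in linked UK sources.
Each source yields its own dated record row, so one fracture can appear
as several same-dated records.

**Missingness.** BMI, smoking, alcohol and ethnicity can be blanked either
MCAR or MAR-on-age, where the blanking probability is
`expit(α + 0.8·(age−60)/10)` with α calibrated by root-finding so the
marginal rate matches the target on the cohort at hand. Default MCAR rates
(BMI 0.30, smoking 0.268, alcohol 0.254) follow the "not recorded" fractions
typical of primary-care baseline tables.

**What the generator does not emulate:** clinical codelists, practice-level
clustering, calendar trends in recording quality, repeated fractures,
within-person covariate change after entry, correlation between
deregistration and frailty, and any dependence of the fracture-kind mix on
age or sex (the composite splits as hip 0.38 / forearm 0.32 / humerus 0.14 /
vertebral 0.16 at all ages). Passing tests therefore demonstrate that the
estimators and the validation logic behave correctly under a faithful
competing-risks data-generating process — not that any particular published
tool is well or badly calibrated on real data.

## Risk equations

An equation is `risk = 1 − S₀(10)^exp(lp)` with `lp` a sum of transformed
continuous terms (fractional-polynomial style: `(x/scale)^power`, `power=0`
meaning `ln`, an optional extra `ln` factor for repeated powers, each
centred by a constant), full-coverage categorical maps (a reference level
with coefficient exactly 0 is enforced), and binary flags. Missing ethnicity
scores as the reference ("white"); any other missing covariate is an error —
prediction runs after imputation. The shipped equations are illustrative
toys whose predictors mirror a routine-data fracture tool; no licensed
coefficients are embedded, because the validation machinery rather than any
coefficient set is the deliverable.

## Outcomes and follow-up

Cohort exit is the earliest of first qualifying fracture record, death,
deregistration, or the study end. Conventions:

* the event date is the *first* record of a qualifying fracture, so
  same-dated multi-source records collapse to one event;
* a fracture and a death on the same date resolve to fracture (death
  registration can itself carry the fracture code);
* an event on the entry date receives half a day of follow-up so times stay
  strictly positive;
* under source restriction, a record counts only if at least one of its
  sources is allowed; a subject whose only fracture record is excluded
  continues to death/censoring.

The Charlson score uses the original 17-condition weight set (1/2/3/6), no
age adjustment, truncated into analysis groups 0/1/2/3+.

## Estimators

Kaplan-Meier and Aalen-Johansen are computed over distinct event times with
the "events before censorings" tie convention; curves are evaluated at a
horizon by the step value at the largest jump ≤ t. The Aalen-Johansen
increments use the all-cause product-limit survival, so
`Σ_k CIF_k + S_all = 1` holds to machine precision at every jump — this is
asserted, not approximated. No interval variances are attached to either
curve in this version (calibration uses point estimates); that is an
extension point.

The Cox fitter is single-covariate Newton-Raphson on the Breslow partial
likelihood, covariate centred internally, convergence at |score| < 1e-8
within 50 iterations with step-halving to keep the likelihood
non-decreasing, standard error from the inverse observed information. It
exists to carry the D statistic; it is cross-checked against an independent
implementation and against a grid-search oracle in the tests.

## Validation metrics

* **Truncated Harrell's C.** Comparable pairs are (i, j) with `t_i < t_j`,
  subject i a fracture event and `t_i ≤ horizon`; competing deaths act as
  censoring (they only ever serve as the later member of a pair). Risk ties
  score 0.5; tied event times are not comparable. The implementation counts
  pairs in vectorised chunks and is tested for exact agreement with an
  O(n²) enumeration. The CI is a 200-replicate nonparametric bootstrap by
  default (configurable) since no analytic CI convention is fixed for the
  truncated statistic.
* **Royston-Sauerbrei D.** Subjects are ranked by predicted risk (ranks of
  the linear predictor would be identical by monotonicity), mapped to Blom
  normal order statistics `Φ⁻¹((r−3/8)/(n+1/4))`, scaled by 1/κ with
  κ = √(8/π); D is the Cox coefficient on that covariate and inherits its
  standard error. For a normal prognostic index of spread σ, D estimates κσ.
* **R²_D** `= 100·(D²/κ²)/(π²/6 + D²/κ²)`.
* **Calibration deciles** are formed within each analysis population by a
  stable sort on (risk, subject id) — reproducible under ties — and report
  mean predicted risk, `1 − S_KM(horizon)` and the Aalen-Johansen fracture
  CIF per decile.

Multiple-imputation runs compute every scalar metric per completed dataset
and pool by Rubin's rules — C on its untransformed scale with bootstrap
variance (the pooling scale for C is not standardised; the untransformed
choice is documented), D with its model-based variance, R²_D transformed
from the pooled D and its interval. Calibration curves pool by averaging
decile summaries. The MI degrees of freedom are
`(m−1)(1 + W/((1+1/m)B))²`, collapsing to the normal quantile when B = 0.

## Imputation model

Chained equations over bmi → smoking → alcohol, default 10 sweeps (the
analysis scripts use 5; the estimand-level results are insensitive to sweep
count once the chain stabilises, usually within a handful of sweeps).
Predictors: entry age, sex, prior fracture, the other two imputed variables,
and optionally an event indicator. BMI uses Bayesian linear regression with
predictive mean matching (5 donors, parameters drawn from the
normal-inverse-χ² posterior each sweep, so Rubin's between-variance is
properly fed); the categorical variables use multinomial logistic regression
on standardised predictors with draws from the fitted probabilities
(parameter uncertainty not re-drawn — a documented approximation that
slightly understates between-imputation variance for category-level
estimands). Deregistered subjects are censored exactly like any other
censoring throughout.

## Numerical and design choices

* All randomness flows from one root seed through spawned generators per
  stage, so any stage is reproducible in isolation; manifests record seeds
  and a configuration hash, and reruns are byte-identical.
* Decile groups use `array_split`, so sizes differ by at most one.
* The demo emulates "derivation on incompletely ascertained data" as
  `1 − exp(−capture·Λ_f(10))`, where Λ_f is the true cumulative fracture
  hazard and capture = 0.85 is the probability a fracture is visible in
  GP + death-certificate records. This is a Kaplan-Meier-style net risk: it
  ignores competing death, exactly as a tool derived without competing-risk
  handling would. Its whole-population check is decile-wise (observed KM
  above predicted in ≥7 of 10 deciles) because the pooled whole-cohort KM
  mixes age strata whose censoring differs.
* Problem sizes in the test suite (50 000 for closed-form recovery, 100 000
  for calibration recovery, 500 replicates for MI coverage) were chosen so
  that each assertion's tolerance corresponds to ≥3 Monte-Carlo standard
  errors, keeping the default run fast and deterministic. In the top
  predicted-risk decile of the calibration-recovery experiment the
  Aalen-Johansen estimate at 10 years has a Monte-Carlo SE of ≈0.004-0.005
  (late-horizon risk sets are thinned by administrative censoring), so the
  0.01 per-decile bound is a ≈2-SE statement there.

## Known limitations

One fracture per subject; constant fracture-kind mix; toy equation
coefficients; no recalibration or model updating; no net-benefit analysis;
no left truncation or multi-state transitions beyond initial → (fracture |
death); KM/AJ curves carry no confidence bands; categorical imputation
omits parameter draws.
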