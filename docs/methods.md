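# Methods

This note documents the statistical procedures, the synthetic-data
design, numerical choices, and what the tests do and do not establish.

## Scoring

The CHARGE-AF equation is evaluated exactly as published: a linear
predictor over eleven scaled covariates mapped through the
baseline-survival power form `1 − S₀^exp(lp − c)`. Missing body
measurements raise an error — the model is only defined for complete
cases, and silent zero-filling would corrupt every downstream
statistic. Ethnicity enters as a constant "white" indicator by default
(configurable per patient): the motivating setting is a Dutch registry
without recorded ethnicity, and dropping the term instead would
systematically underestimate absolute risk.

Risk categories use cut-offs 2.5% and 5% by default. Boundary
convention: interior thresholds are closed on the left and the top
threshold value still belongs to the middle band, so 2.5% and 5.0%
both read as "intermediate" — matching the conventional "2.5%–5%"
interval notation. CHA₂DS₂-VASc uses completed years for its age
bands; "vascular disease" means myocardial infarction, atherosclerotic
arterial disease or angina, each derived from configurable code sets.

## Cohort construction

Baseline covariates come from the measurement entry closest to the
baseline date within a one-year window (ties on the same day: the
lexicographically smaller value, making extraction deterministic and
order-independent). Morbidity flags are true when any mapped episode
starts before baseline — no lookback limit, which, combined with the
one-year measurement window, reproduces the effective behaviour of
registries that deactivate episodes after a contact-free year.
Antihypertensive use requires a prescription inside the baseline-year
window. Eligibility: age ≥ 40 completed years, registered all four
baseline-year quarters, no AF episode before baseline. Complete cases
have all of height, weight, SBP and DBP recorded in the window.

## Follow-up and censoring

Registration is quarterly. Loss to follow-up is the first day of the
earliest run of ≥ 4 consecutive absent quarters, or of a trailing
absent run reaching the end of the observation window. Follow-up ends
at the earliest of AF diagnosis, loss, or the 5-year window end; on
date ties the censoring mechanisms win, because an AF code dated on or
after the loss date falls in the unregistered period and a code on the
window-end date is outside the half-open observation interval. Time
uses 365.25 days per year. Death is not distinguishable from other
loss; there is no competing-risk adjustment — cumulative incidences
are Kaplan–Meier failure probabilities.

The Kaplan–Meier estimator is the standard product-limit with events
preceding censorings in tied risk sets; Greenwood's formula supplies
the variance, and calibration CIs are plain normal intervals on the
failure scale (clipped to [0, 1]). It is implemented directly so the
variance and tie conventions are explicit; the test-suite cross-checks
it against both a brute-force risk-set product and `lifelines`.

## Validation statistics

**Concordance.** Harrell's C over usable pairs (the earlier observed
time an event; tied times usable only when exactly one is an event, the
event counted as earlier; tied markers ½). The point estimate is
computed by `lifelines`; the 95% CI is a seeded patient-level
percentile bootstrap (default B = 200). The CI method is a design
choice — the bootstrap keeps the concordance and NRI machinery uniform.

**Calibration.** Patients are ranked by predicted risk (stable sort,
so tied risks keep input order and decile membership is reproducible)
and split into ten near-equal groups; each group contributes its mean
predicted risk and KM-observed failure at the horizon. The
Nam–D'Agostino statistic is
`χ² = Σ n_g (KM_g − p̄_g)² / (p̄_g (1 − p̄_g))`.

Degrees of freedom: in *external* validation no parameter is estimated
on the validation data, so each group term is asymptotically an
independent χ²₁ and the statistic is χ² with **G** degrees of freedom.
The classic G−1 convention (appropriate when groups derive from model
development) inflates the type-I error to ≈ 7.6% at G = 10; the
package's 500-replicate null simulation confirms the nominal 5% level
with df = G, which is therefore the default (`df_reduction=1` restores
the classic convention). Note the default denominator is the binomial
variance at the group mean: under heavy censoring the true KM variance
exceeds it, so the test is anti-conservative in strongly censored data
— the statistic's level simulation is run without censoring for this
reason. `nam_dagostino(..., variance="greenwood")` divides each group
term by its Greenwood variance instead, the censoring-aware variant
used in the survival-calibration literature; the generator's own
calibration-null check uses it because the default synthetic world
censors ~30% of follow-up.

**Calibration slope.** The coefficient of the model's linear predictor
in a single-covariate Cox refit (1 = ideal, < 1 = overfitting /
overdispersion). The partial likelihood uses the Efron tie correction
— quarterly EHR data are heavily tied — maximised by damped
Newton–Raphson (tolerance 1e-9 on the step, max 50 iterations),
standard errors from the observed information. Monotone likelihoods
(complete separation) and singular information raise explicit errors.
The covariate is mean-centred internally for conditioning; estimates
are invariant.

**Comparator predictors.** Age alone and CHA₂DS₂-VASc are placed on
the absolute-risk scale for reclassification analysis by a
single-covariate Cox fit plus the Breslow baseline cumulative hazard
at the horizon: `risk = 1 − exp(−H₀ exp(b(x − x̄)))`. This mapping is a
design choice (the convention in the source setting is unstated); it
preserves the marker's ordering exactly, so it cannot flatter the
comparator's discrimination.

**NRI.** Categorical net reclassification improvement with
censoring-aware event estimation: category cross-classification, then
KM failure at the horizon *within* the up- and down-reclassified sets,
giving `NRI_events = [P(up)·p_up − P(down)·p_down]/p_all` and the
mirror-image non-event component; the two components sum to the
overall index by construction. Without censoring this reduces exactly
to the contingency-table formula (tested). CI by seeded percentile
bootstrap, B = 200.

All bootstrap randomness flows from one integer seed (default
20140101, the baseline date).

## Synthetic cohort generator

The generator emulates the statistical regime of a complete-case
validation study in routine primary-care data. Its defaults are the
stated world of that setting: complete cases average 65.5 years
(SD 11.4, truncated at 40), 52.5% female; measurement marginals
170.0±9.9 cm, 82.5±16.8 kg, 137.3±16.3 / 80.5±10.5 mm Hg; population
comorbidity prevalences 70.9% antihypertensive use, 66.5% hypertension,
42.7% diabetes, 4.2% heart failure, 4.9% MI, 14.2% smoking, 6.7%
stroke, 3.0% TIA, 5.7% atherosclerosis, 9.1% angina; 17.2% complete
cases; 4.7% complete-case 5-year AF incidence; 3.5-year mean observed
follow-up.

Design:

- **Covariates.** Age from a truncated normal (completed years);
  comorbidities from logistic-in-age models whose intercepts are solved
  by root-finding on the realized population mean. Age slopes (log-odds
  per year: 0.05–0.10 for cardiovascular morbidity, −0.04 for current
  smoking) are plausible-magnitude defaults, stated once in
  `GeneratorConfig`; they shape the MNAR selection below but no
  headline target depends on their exact values. Height/weight and
  SBP/DBP are correlated normals (ρ = 0.5 each, configurable) with
  sex-specific location offsets chosen to preserve the overall
  marginals. Comorbidities are conditionally independent given age — a
  deliberate simplification.
- **Missingness.** P(all four measurements recorded) is logit-linear
  in cardiovascular comorbidity count (slope 0.25) and age (0.02/year),
  the intercept solved for a 17.2% complete fraction. Because sicker,
  older patients are more often complete, the population age location
  is then solved (outer root-find) so the *complete-case* mean age
  lands on 65.5 — the baseline table of a complete-case study describes
  that subset, not the population. Incomplete cases have 1–4 of the
  four measurements blanked uniformly.
- **Events.** Each patient's hazard is constant,
  `λ = −m·ln(1 − p)/5` with p their (optionally distorted) predicted
  5-year risk. Since `−ln(1 − p) = exp(lp − c)·(−ln S₀)`, the process
  is *exactly* proportional hazards in the linear predictor — slope
  recovery is a well-posed parameter-recovery check, not an
  approximation. The multiplier m acts on the hazard scale (5-year risk
  `1 − (1−p)^m`) and is solved so expected complete-case incidence hits
  4.7%; any hazard shape matching S(5) would be observationally
  equivalent at the horizon. Miscalibration knobs distort the
  generating linear predictor (slope, intercept) for power studies.
- **Censoring.** Absorbing per-quarter dropout (geometric first absent
  quarter, never the baseline quarter), solved so mean observed
  complete-case follow-up is 3.5 years; optional practice-level dropout
  blocks cluster losses by practice. Dropout is independent of
  covariates and event risk, so KM estimates are unbiased.
- **Determinism.** All random deviates are drawn once from seeded
  streams; every solver evaluates against those fixed deviates, so
  regeneration with the same config and seed is bit-identical, and the
  provenance hash covers the full config.
- **Raw-record emission.** The flat cohort can be re-expressed as
  dated EHR-like records (measurements with decoy earlier entries,
  pre-baseline episodes, prescriptions, registration grids); the
  round trip through baseline extraction and the follow-up rules
  reproduces the flat table exactly, exercising the whole ingestion
  path.

### What the defaults imply (and what a green test does not establish)

The solved hazard multiplier at defaults is ≈ 0.47: with these
covariate marginals the mean model-predicted risk among complete cases
is ≈ 9%, so matching the 4.7% incidence target necessarily makes the
published model *overestimate* absolute risk on the synthetic data —
the same regime the motivating validation reported (slope ≈ 0.69,
overestimation in the top deciles). Consequently:

- the "well-calibrated null" checks (Nam–D'Agostino level, calibration
  table) refer to the **generating** risk, which the frame stores next
  to the model's `true_risk`;
- the calibration slope of the true linear predictor is ≈ 1 at
  defaults regardless of the multiplier (proportional scaling moves
  only the baseline hazard);
- the c-statistic of true risk at defaults is ≈ 0.83 — *higher* than
  the ≈ 0.74 seen on real data, because a well-specified generator has
  no residual heterogeneity. Injecting the observed slope regime
  (`lp_slope_distortion=0.69`) yields c ≈ 0.75 and a recovered slope
  ≈ 0.69 simultaneously, i.e. the real-data discrimination and slope
  are jointly explained by miscalibration-like dispersion. Green
  generator tests therefore certify internal consistency of the
  simulated world, not agreement with any licensed dataset's headline
  results.

The generator reproduces only the configured marginals, correlations
and selection structure — not the full joint distribution of any real
registry; incomplete-case event rates follow from the MNAR slopes
rather than an external target.

## Numerical choices

- Root solvers: Brent's method throughout; logistic intercepts to
  1e-9, population age mean to 5e-3 years, dropout probability to
  1e-10 (the realized mean follow-up is piecewise constant in q, so
  the solve lands within one quarter-step of the target).
- Cox: Newton steps halved while the log-likelihood decreases;
  |β| > 500 is declared a monotone likelihood.
- KM at a group with zero at-risk at the horizon start simply reports
  the last attained failure value; degenerate calibration groups
  (mean predicted 0 or 1) are dropped from the χ² with a warning.
- Decile ties are broken by stable input order, so repeated runs give
  identical groupings.

## Known limitations

- No competing risks: death is folded into loss to follow-up, as in
  the motivating registry, so "5-year incidence" is a cause-naive KM
  failure probability.
- The Nam–D'Agostino denominator understates the variance of heavily
  censored KM estimates (see above).
- The synthetic world is conditionally independent given age and uses
  a single dropout mechanism; real registries have richer dependence
  and practice-level exit waves (a simple practice-block option is
  provided).
- Exact diagnosis/medication code lists are configuration; the shipped
  ICPC-1/ATC defaults are placeholders for real operational lists.
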