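# chargeaf

External validation of the CHARGE-AF 5-year atrial-fibrillation risk
model on routine primary-care electronic health records — as a tested,
reusable Python pipeline.

Atrial fibrillation (AF) is common, often silent, and raises stroke
risk; screening programmes want to invite the patients most likely to
develop it. The CHARGE-AF equation predicts an individual's absolute
5-year risk of new AF from eleven routinely available covariates. This
package is for biostatisticians and screening researchers who want to
(1) compute CHARGE-AF and CHA₂DS₂-VASc scores from EHR-style baseline
data, (2) validate the model against censored follow-up with the
standard toolkit — concordance, calibration, reclassification — and
(3) explore what different risk cut-offs would mean for patient
selection. Because the motivating data source (a national primary-care
registry) is license-restricted, the package ships a calibrated
synthetic cohort generator so the entire pipeline runs end-to-end with
no data download.

## The model

CHARGE-AF predicts the 5-year AF probability as

```
risk = 1 − S₀ ^ exp(Σ bX − c),      S₀ = 0.9718412736,  c = 12.5815600
```

with the linear predictor

```
Σ bX = (age/5)·0.5083 + white·0.46491 + (height/10)·0.2478
     + (weight/15)·0.1155 + (SBP/20)·0.1972 − (DBP/10)·0.1013
     + smoking·0.35931 + antihypertensive·0.34889 + diabetes·0.23666
     + heart failure·0.70127 + myocardial infarction·0.49659
```

(age in years, height cm, weight kg, pressures mm Hg). Validation
statistics implemented for right-censored outcomes: Harrell's
C-statistic with bootstrap CI, calibration tables over risk deciles
(Kaplan–Meier observed vs mean predicted, Greenwood CIs), the
Nam–D'Agostino χ² calibration test, the calibration slope (Cox refit
of the linear predictor, Efron ties), categorical net reclassification
improvement under censoring, risk-stratified Kaplan–Meier curves, and
screening-triage tables with unadjusted hazard ratios.

## Worked example

Score one patient:

```python
from chargeaf import charge_af_linear_predictor, charge_af_risk, cha2ds2_vasc

cov = dict(age_years=70, sex="female", ethnicity_white=True,
           height_cm=168, weight_kg=78, sbp_mmHg=140, dbp_mmHg=85,
           current_smoking=False, antihypertensive_use=True,
           diabetes=False, heart_failure=False, myocardial_infarction=False,
           hypertension=True, stroke=False, tia=False,
           atherosclerosis=False, angina=False)
lp = charge_af_linear_predictor(cov)
print(lp, charge_af_risk(lp), cha2ds2_vasc(cov))
# 13.2130  0.0523  3
```

A 70-year-old woman on antihypertensives has linear predictor 13.21 and
a predicted 5-year AF risk of 5.2% — just above the 5% cut-off, so
"high risk" under the default three-band categorisation — with a
CHA₂DS₂-VASc of 3 (age band 1, hypertension 1, female 1).

Validate the model on a synthetic cohort:

```python
from chargeaf import generate_cohort, GeneratorConfig, score_cohort
from chargeaf.validation import harrell_c, cox_fit_single
from chargeaf.triage import triage_table

cohort = generate_cohort(GeneratorConfig(n=50_000, seed=20140101))
comp = score_cohort(cohort.complete.reset_index(drop=True))
t, e = comp["time_years"].to_numpy(), comp["event"].to_numpy()

harrell_c(comp["charge_af_risk5y"].to_numpy(), t, e)
# CStatistic(c=0.827, ci_low=0.804, ci_high=0.850, n_bootstrap=200)
cox_fit_single(comp["charge_af_lp"].to_numpy(), t, e).coefficient
# 0.95  (calibration slope; 1 = ideal)
triage_table(comp, [0.025, 0.05, 0.10])
#  cutoff  pct_high  sensitivity  cumulative_incidence_high  hr_high_vs_low
#   0.025     0.657        0.976                      0.069          22.3
#   0.050     0.448        0.875                      0.090           8.9
#   0.100     0.250        0.703                      0.129           7.5
```

Reading the triage table: screening everyone above 2.5% predicted risk
would flag 65.7% of complete cases and capture 97.6% of the AF cases
observed within five years, at a 6.9% incidence in the flagged group;
raising the cut-off to 10% flags a quarter of patients with a 12.9%
incidence but misses 30% of cases. The same pipeline is available from
the shell:

```sh
chargeaf simulate --n 50000 --seed 20140101 --output-dir run/
chargeaf validate --input run/cohort.csv --output-dir run/report/
chargeaf triage --input run/cohort.csv --output run/triage.csv
```

Real data enter either as a flat per-patient CSV (columns named as in
`chargeaf.io.COHORT_COLUMNS`, plus `time_years`/`event`/`censor_reason`)
or as four raw CSVs (episodes, measurements, prescriptions,
registration; see `chargeaf.io`) from which baseline covariates,
eligibility and censored outcomes are derived. Diagnosis/medication
code sets are configuration (`chargeaf.cohort.CodeMap`); the shipped
ICPC-1/ATC defaults must be replaced by your database's operational
lists.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch, the constants and generator calibration
targets: the baseline-survival constant implied by the risk equation,
and — from a fresh default synthetic cohort of 100 000 patients under
the given seed — the complete-case mean age, female percentage,
Kaplan–Meier 5-year AF incidence, complete-case percentage, and mean
observed follow-up. Results are written as JSON to `--out`.

## Layout

- `src/chargeaf/risk.py` — CHARGE-AF / CHA₂DS₂-VASc scoring, risk
  categories, contribution decomposition
- `src/chargeaf/cohort.py` — raw-record baseline extraction,
  eligibility, complete-case split, group comparison
- `src/chargeaf/followup.py` — quarterly loss-to-follow-up rule,
  outcome resolution, Kaplan–Meier with Greenwood variance
- `src/chargeaf/validation.py` — concordance, Cox fits, calibration,
  Nam–D'Agostino, NRI, stratified reports
- `src/chargeaf/triage.py` — screening cut-off tables
- `src/chargeaf/synthetic.py` — calibrated synthetic cohort generator
- `src/chargeaf/io.py`, `src/chargeaf/cli.py` — CSV schemas and CLI

See `docs/methods.md` for the statistical methods, generator design and
known limitations.
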