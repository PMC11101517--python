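# Methods

`bbemu` implements, as reusable library code, a complete observational
emulation of a pragmatic trial of long-term oral beta blockers versus no
beta blockers after myocardial infarction with preserved ejection fraction,
of the kind run on nationwide cardiac-care registries linked to prescription
and population registers.  Because such registry data cannot be shipped, the
package pairs the analysis pipeline with a synthetic-registry generator that
reproduces the statistical structure the analysis has to confront —
confounded prescribing, refill-based adherence, competing events — together
with a counterfactual oracle that knows the true effects, so every stage of
the pipeline can be validated by parameter recovery.

## Study design being emulated

**Eligibility.** Persons hospitalized for a type-1 MI with coronary
angiography, screened over a fixed recruitment window.  Exclusions, applied
in a fixed, logged order with a selection flowchart: (1) no angiography
within the assignment window of the index event; (2) a beta-blocker
contraindication (bradycardia, AV block II–III, hypotension, syncope,
asthma, COPD, stroke) diagnosed in the 3 years before angiography; (3) an
indication for beta blockers other than secondary prevention — prior
beta-blocker use (dispensation history and/or admission record), heart rate
≥ 120, systolic BP ≥ 180, diastolic BP ≥ 120, chronic heart failure or
atrial flicker/flutter; (4) conditions limiting protocol compliance
(psychiatric disorder, dementia); (5) not on both statins and
antithrombotics by time zero; (6) death or new MI inside the assignment
window.

**Assignment and time zero.** Treatment "assignment" is operationalized as
a beta-blocker (metoprolol or bisoprolol) dispensation strictly after
angiography and within 30 days; if no dispensation exists but the discharge
record indicates a beta blocker, the discharge date (modelled as
angiography + 3 days) is used.  Time zero is a landmark at angiography + 30
days for both arms, with window events excluded; the misalignment this
introduces is probed by the clone-censor sensitivity analysis.  Whether
follow-up in such emulations should start at angiography, at prescription,
or at the window end is genuinely open; the landmark reading is one
defensible choice and is kept fixed rather than silently varied.

**Adherence.** Each dispensation covers
`floor(pill_count × pill_dose / daily_dose)` days, with assumed daily doses
of 100 mg metoprolol and 5 mg bisoprolol.  Early refills extend coverage
(stockpiling; a no-stockpiling mode exists).  A treated person deviates at
the first refill gap of ≥ 180 days (90 in a sensitivity variant), censored
at *last covered day + gap_days* — the first day the gap criterion is
violated — unless a contraindication diagnosis on or before that coverage
end excuses it.  An untreated person deviates at the first beta-blocker
dispensation after time zero, unless preceded by a new-indication diagnosis
(hypertension, angina, arrhythmia, heart failure).  A treated subject with
no coverage at all starts the deviation clock at time zero.

**Outcomes and person-time.** Death, new MI, and their composite, on a
discrete grid of 30.4375-day "months" (365.25/12) with a 60-interval
(five-year) horizon and administrative end of study.  A person censored
mid-interval contributes only complete intervals (floor rule); events
always close their interval.  For the *total effect* on MI, death does not
end follow-up: the person contributes MI = 0 intervals thereafter, giving a
cumulative-incidence-type risk; artificial censoring applies only while
alive.  Same-interval death and MI count as MI for the MI outcome, death
for the death outcome, and a single event for the composite.

**Estimation.** The discrete-time hazard is fit by weighted
maximum-likelihood pooled logistic regression: event indicator on assigned
arm, a restricted cubic spline of interval (knots at 6, 12, 24, 48 months)
and arm × spline product terms (full interaction with the time basis).
Cumulative risk follows the product-limit recursion
`risk(t) = 1 − Π_{s≤t}(1 − hazard(s))`.  Five-year risks are compared by
difference and ratio; an average hazard ratio at 3, 4 and 5 years comes
from the same model *without* product terms, refit on person-time truncated
at each horizon (not by integrating the 5-year fit).  When baseline
covariates enter the outcome model instead of weights (sensitivity 1),
risks are standardized by the parametric g-formula: per-subject risk curves
under each arm are averaged over the empirical covariate distribution.

**Weights.** Intention-to-treat: stabilized inverse-probability-of-
treatment weights, `P(A=a) / P(A=a|L)`, with the denominator from a
logistic regression of arm on the 12 default baseline covariates
(categoricals as indicators against the most frequent level).
Per-protocol: additionally, time-varying stabilized inverse-probability-of-
censoring weights fit per arm — denominator: baseline covariates +
time-varying covariates (renal-disease diagnosis carried forward;
current-interval dispensation of ARB, ACE inhibitor, CCB, diuretic,
nitrate, diabetes treatment) + spline of interval; numerator: the same
without the time-varying block; cumulative weight = running product of
numerator/denominator probabilities.  The per-protocol combined weight is
the baseline weight times the cumulative censoring weight.  Weight
truncation is off by default (a mirrored-percentile option exists, e.g.
99.5).  Censoring-hazard fits carry a weak L2 penalty (unit ridge,
intercept excluded): censoring events are sparse per interval and
quasi-separation is routine, so an unpenalized MLE need not exist; the
penalty is negligible for identified coefficients and is applied only in
these models.

**Inference.** Nonparametric bootstrap over persons with percentile 2.5/97.5
intervals (500 resamples by default; smaller sizes are used where noted).
Every weight model is re-estimated inside each replicate, so the weights'
estimation uncertainty enters the intervals.  Replicates that fail to
converge are dropped and counted; more than 5% failures is an error.  For
speed, replicates reuse pre-expanded person-interval blocks and collapse the
outcome model to (arm, interval) grouped-binomial cells, which is exact:
the design depends only on arm and time, so rows sharing a cell contribute
identically to the likelihood.

**Sensitivity analyses.** (1) covariate-adjusted outcome model instead of
IP weighting; (2a) retain prior beta-blocker users, adding a prior-use
indicator (either source) to the covariate set; (2b) exclude on the
admission record only, adjusting for dispensation-history prior use;
(3a) complete-case analysis; (3b) continuous covariates binned into
quintiles plus a "missing" level; (4) clone-censor-weight analysis (below);
and the per-protocol 90-day-gap variant.  The grid records each variant's
exact config delta.

### Clone-censor-weight analysis

Baseline alignment is re-examined by moving time zero back to angiography.
Eligibility is evaluated at angiography (the statins/antithrombotics-at-
day-30 and event-free-window criteria are dropped, since they post-date
time zero).  Every eligible person contributes two clones.  The initiation
clone is censored at the end of a 30-day grace period if no beta-blocker
dispensation occurred by then; the no-initiation clone is censored at the
first dispensation inside the grace window; events on or before the
deviation day count for the clone.  Inverse-probability-of-censoring
weights over the window come from per-clone-arm logistic models on baseline
covariates.  The grace window is modelled as a single nonparametric
discrete interval (weighted event proportion per clone arm) and composed
with a pooled logistic fit on the post-window person-time, which runs on
exactly the landmark grid:
`risk(t) = 1 − (1 − r_window) × (1 − risk_post(t))`.

This construction has a useful exactness property: with no window events
and no misalignment, the post-window clone dataset coincides with the
landmark dataset, and because the outcome model is saturated in arm
(arm main effect plus full arm × time interaction), per-arm constant
rescaling of weights does not move the MLE — so the clone-censor risks
reproduce the landmark risks to solver precision.  With elevated event
hazard inside the window, the clone analysis includes those events and its
risks exceed the landmark ones.  This recipe is this package's own
formalization of the clone-censor-weight idea for a 30-day grace period; it
is one standard variant among several.

## Synthetic registry

The generator simulates event histories directly on the analysis grid, so
the oracle recursion is exact there; dates are synthesized at the
mid-interval day, which maps back to the generating interval under the
analysis' flooring rule.

* **Covariates** (12 defaults): age, sex, smoking (3 levels), hypertension,
  diabetes, previous MI, heart-failure history, infarction type, heart
  rate, systolic BP, LDL, creatinine, with marginals near those reported
  for post-MI cohorts with preserved ejection fraction.  Continuous
  covariates enter all internal models standardized, so coefficients are
  per-SD log-odds.
* **Assignment**: logistic in the covariates; the default intercept yields
  roughly a 9:1 treated:untreated split, as seen in practice.
* **Events**: per-interval logistic hazards for death and first MI with a
  treatment log-odds-ratio *of the assigned sustained strategy* (defaults
  ln 0.90 for death, ln 0.75 for MI).  MI may share death's interval.
  Time-varying renal disease (baseline prevalence 1.3%, onset 0.002 per
  interval) raises both hazards.
* **Adherence**: treated persons stop refilling with a per-interval
  discontinuation hazard (logit −4.4, renal +1.0) and occasionally resume
  after a long gap (probability 0.004 per refill); untreated persons
  cross over with per-interval logit −4.85.  30% of discontinuations are
  preceded by a contraindication diagnosis, 50% of crossovers by a
  new-indication diagnosis, so both excusal branches of the adherence rule
  are exercised.  These rates were calibrated once so that observed
  follow-up adherence lands near 74% / 91% in the two arms, and then
  frozen.
* **History**: 3-year pre-baseline dispensations (statins/antithrombotics
  for 94% of persons, prior beta blockers for 10% with an admission-record
  flag agreeing 90% of the time) and lookback diagnoses at fixed per-person
  rates, so every eligibility rule fires on someone.
* **Missingness**: independent blanking of continuous labs (15.5% LDL,
  4.4% creatinine by default), injected by a separate operation so the
  complete data remain available to tests.

**What it does not emulate**: real ICD-10/ATC coding (conditions are
symbolic codes), hospital clustering, within-person correlation of refill
timing beyond the discontinuation process, migration, dose tapering, or
measurement error in covariates.  Passing recovery tests therefore shows
the estimators are correct under the assumed data-generating structure —
correctly specified weight models, discrete-time hazards, exchangeability
given measured covariates — not that those assumptions hold in any real
registry.

**Counterfactual oracle.** `compute_true_effects` simulates, for each
oracle person, both counterfactual event histories (always treated from
time zero; never treated) with adherence forced perfect and no
administrative censoring, and tabulates marginal risks per interval with
binomial Monte-Carlo standard errors.  Because the effect is attached to
the assigned sustained strategy, the oracle risk is both the true ITT
estimand and the always-adherent (per-protocol) estimand.

## Numerical choices

* Logistic fits use Newton–Raphson with step-halving on grouped-binomial
  data (fractional responses with case weights), converging on the
  penalized log-likelihood to 1e-10 relative; non-convergence or fitted
  logits beyond ±30 raise an estimation error naming the worst columns.
  The solver is cross-checked against statsmodels GLM in the test suite.
* Saturated-time ("nonparametric") fits are computed directly as weighted
  event proportions per (arm, interval) cell — the closed form of the MLE
  on that design — and reproduce the Kaplan–Meier product-limit estimator
  exactly (verified against lifelines to 1e-10).
* Ties: a dispensation on the angiography day counts as *prior* use
  ("after" means strictly later); an event on the same day as a deviation
  counts as an event.
* Degenerate inputs: empty cohorts produce empty tables; an empty arm is a
  positivity error; a covariate that is entirely missing is an imputation
  error naming the covariate; a zero-censoring arm gets unit weights with a
  log note rather than an error.
* Reproducibility: one global seed fans out to named substreams
  (covariates, history, assignment, events, adherence, drugs, window,
  oracle, bootstrap), so reruns are bit-identical per stage.

## Problem sizes

Statistical checks in the test suite use the smallest sizes at which their
properties are decisive: confounding-null and per-protocol weighting at
n = 20,000; effect recovery at n = 50,000 with a 50,000-person oracle;
bootstrap coverage with 200 simulation replicates of n = 2,000 and 200
bootstrap resamples against a 100,000-person oracle; clone-censor
consistency at n = 6,000.  `scripts/acceptance.py` reports the full
pipeline at n = 5,000 with 200 (ITT) / 60 (per-protocol) bootstrap
resamples and a 50,000-person oracle.

## Known limitations

* The per-protocol censoring weights use a half-interval convention: the
  last complete interval of a censored person is both an at-risk outcome
  interval and the censoring-model event row.
* After death, artificial censoring is undefined and is not applied (the
  MI total-effect expansion keeps the person uncensored to the horizon).
* Cumulative-incidence coherence across the three outcomes holds exactly
  for true risks and for the lower bound of the nonparametric estimates;
  the upper bound (composite ≤ MI + death) holds for estimates only up to
  sampling noise because the three expansions use different risk sets.
* The bootstrap treats the cohort as i.i.d. persons; no clustering by
  hospital or calendar period is modelled or resampled.
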