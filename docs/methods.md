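# Methods

This note records the modelling choices, parameter defaults, and numerical
conventions behind `opioidcohort`, and what the synthetic data can and
cannot show about real registry linkages.

## Conventions

All dates are ISO-8601; every interval is half-open `[start, end)`. ICD-10
codes are compared by prefix after normalization (uppercase, dots removed),
so a 4-character category such as `T40.1` matches a 7-character claim code
`T40.1X1A`. "12 months" is implemented as 365 days, "6 months" as 183 days
(insurance-plan attribution and the secondary-outcome window); the
literature rarely states which day-count convention was used, so these are
package conventions, configurable where they matter.

## Cleaning

Cleaning removes, with one reason per row and a fixed precedence
(duplicate → missing prescriber → quantity → days' supply): exact duplicate
rows (identical on all dispensing fields), fills without a prescriber ID,
quantities < 4 or ≥ the 99th-percentile cutoff, and days' supply outside
[0, 90]. The quantity cutoff is computed **once** over the full input fill
set before any filter and can be frozen explicitly; this makes cleaning
idempotent (re-cleaning a cleaned set with the frozen cutoff removes
nothing) and reproducible. The cutoff is global rather than per-drug. Note
that on very small inputs an empirical ≥-percentile rule necessarily flags
the largest fill; the rule is intended for registry-scale data.

## Cohort

Index candidates are non-long-acting hydrocodone/oxycodone fills in
2015–2017. The naïve lookback scans *all* opioid fills (any ingredient,
including long-acting) and all ED/inpatient claims whose diagnoses match the
overdose code prefixes, in `[index − 365 d, index)`; same-day records do not
disqualify (the lookback is strictly before the index day). The earliest
qualifying candidate per patient is the index event.

Enrollment continuity is evaluated within the index calendar year only:
every gap — year start to first span, between spans, last span to year end —
must be < 90 days. For patients who died in the index year the evaluation
window is truncated at the death date, so a patient continuously enrolled up
to death is retained. Whether a gap straddling a year boundary should count
is undefined in year-level terms; we count only within-year gap days.

Covariate coding: age in the 7 standard bins (against a configurable
reference date); MME binned at fixed breakpoints {75, 100, 200, 300} —
reported sample quartiles/90th percentile of this population, frozen as
defaults so outputs are comparable across runs (a data-driven percentile
mode can be had by passing recomputed breakpoints); days' supply {≤3, 4–6,
7+}; insurance is the plan covering ≥ 183 days of the index year (ties
broken by covered days, then a fixed plan order), else "unknown".

## Outcomes

**Chronic use.** Uncovered days between consecutive fills are
`max(0, next − (current + supply))`; early refills are clipped at zero
rather than banked, because "uncovered" cannot be negative and the
definition is gap-wise. The terminal gap substitutes day 365 and is clipped
at zero too when coverage extends past the window. The average divides total
uncovered days by the number of inter-fill gaps plus one. The package's gap
arithmetic is validated against an independent day-by-day simulator in which
coverage *restarts* at each fill (the most recent fill determines coverage);
under that restart semantics the two computations agree exactly, which the
test suite asserts over randomized trajectories. Under these conventions the
primary definition mathematically implies the alternative one (coverage ≥
185 days forces an episode > 90 days and a total supply ≥ 185), so the
definition-overlap helper reports 100% in one direction on our data; real
data processed with different gap conventions need not behave this way.

**Overdose.** Fatal detection requires the underlying-cause/multiple-cause
code combination or a lowercase substring match of the death-certificate
literal text against a configurable term list (default: heroin, fentanyl,
opioid, opiate, oxycodone, hydrocodone, morphine, methadone). A dedicated
literal-text classification tool is out of scope; the keyword matcher is a
deliberate simplification. Non-fatal detection is any T40.0–.4/.6 prefix in
ED/inpatient diagnoses. The earliest event on/after the index date wins;
same-day fatal records outrank claims.

**Survival.** The censor date is the earliest of: overdose (event),
December 31 preceding the first post-index calendar year failing the
enrollment-gap rule, non-opioid death, or 2018-12-31. The death-year
continuity check is truncated at death, mirroring the inclusion filter. On
same-day ties the priority is event → study end → death → enrollment loss,
which preserves the invariant that survival equals the index→study-end span
only under study-end censoring.

**Secondary outcomes.** Cumulative MME sums per-fill MME over
`(index, index + 183 d)` — the index day itself is excluded. Switching
compares base opioid ingredients only (oxycodone-APAP → oxycodone
monotherapy is not a switch) and is missing for patients with no additional
fill. A sensitivity helper flags patients who died within 365 days of index
for exclusion.

## Models

Reference levels are fixed (hydrocodone SA; age 18–24; male; White;
commercial; noncore; 2015; MME ≤ 75; ≤ 3 days). All intervals are Wald on
the log scale, `exp(β ± 1.96·SE)`; no multiple-testing adjustment. Terms
with |β| > 10 or SE > 50 are treated as separation artifacts and withheld.

* **Chronic use / switching:** maximum-likelihood logistic regression; with
  the prescriber random intercept, a variational-Bayes mixed binomial GLM
  (the estimation method is recorded in each report; variational posterior
  SDs are known to be slightly anti-conservative). A degenerate grouping
  (< 2 prescribers) falls back to the single-level fit, recorded as a
  warning.
* **Overdose:** Cox proportional hazards with Efron tie handling. The
  high-volume-prescriber subgroup (≥ 200 patients by default) adds a shared
  gamma frailty estimated by EM: the E-step computes group frailty
  expectations from event counts and accumulated cumulative hazards, the
  M-step refits the partial likelihood with log-frailty offsets and
  maximizes the gamma profile for the frailty variance. Covariate levels
  with no events are dropped with a warning; an all-censored input yields a
  flagged report with no estimates.
* **Cumulative MME:** zero-inflated negative binomial (NB2) on MME rounded
  to integer units; the inflation portion reports odds ratios of a zero
  6-month total, the count portion rate ratios. Non-convergence triggers a
  staged fallback — separate logistic (zero) and truncated NB (count)
  models — recorded in the report method string.

## Synthetic data

Two generation paths serve different purposes.

`generate_population` emits the four linked tables mechanistically. Chronic
use is **not** stamped as a label: each patient has a per-fill continuation
probability (logit = intercept + scaled covariate effects + a latent
heaviness frailty), refill chains are geometric with a cap of 20 fills, and
heavier patients draw longer "maintenance" days' supplies, so the chronic
definitions emerge from trajectories. Overdose times are exponential with
configured covariate log hazard ratios; fatal overdoses emit qualifying
death records (a configurable fraction detectable only through literal
text), non-fatal ones emit T40.x claims; enrollment churn fails whole
post-index years; background mortality, pre-index history, duplicate rows,
and missing prescribers exercise every exclusion path. Defaults were chosen
once to emulate the study conditions: 68% hydrocodone share, oxycodone
shifted toward higher MME and longer supplies, ~2.8% chronic use, ~42% of
patients with a second fill, ~38% switching among them, ~0.3% overdose,
~1.3%/year background mortality, and effect sizes at the published adjusted
estimates (chronic log-OR log 0.95 with an MME gradient that reverses the
unadjusted association; subgroup overdose log-HRs log 1.26 / log 2.18 and
log 1.65 otherwise; zero-MME log-OR log 0.88; count log-RR log 1.20; switch
log-OR log 1.24).

`generate_model_frame` draws each outcome directly from the parametric form
the corresponding estimator assumes (logistic, exponential hazard with
calendar censoring, ZINB, logistic), sharing the covariate sampler. This is
the path used for null-recovery and parameter-recovery simulation, where
the estimand must equal the configured coefficient exactly; the mechanistic
path cannot guarantee that (a continuation process does not induce an exact
logistic law for the chronic flag), and using it there would conflate
generator mis-specification with estimator error.

What passing tests do **not** show about real data: the generator has no
record-linkage error, no NDC dialects, no informative prescriber behavior,
no geographic or drug-market structure, and independence assumptions
(censoring independent of the event given covariates) that real enrollment
dynamics may violate.

## Problem sizes and runtime choices

Recovery suites run 50 replicates at n = 20,000 (logistic null) and
n = 50,000 (Cox, ~150 events per replicate, coverage asserted at the
binomial tolerances); the sign-flip check averages 10 replicates at
n = 50,000; subgroup ordering uses one n = 100,000 replicate; generator
fidelity checks use an elevated event rate so the person-time hazard-ratio
estimate is precise enough for a 15% band. Mechanistic end-to-end tests run
at n = 1,500–6,000. These sizes keep the full suite around two minutes on
one CPU while leaving each assertion comfortably inside its statistical
tolerance.

## Known limitations

* The frailty EM reports Wald SEs from the final offset fit, which ignores
  uncertainty in the frailty variance; on sparse events the variance
  estimate can collapse toward zero.
* The variational mixed-logistic CIs are narrower than likelihood-based
  ones; the single-level fit is the default in the pipeline.
* The keyword literal-text matcher will over-match terms appearing in
  negated or incidental phrases; real literal-text processing needs a
  dedicated tool.
* MME accounting covers tablet-form opioids only (mg × count × factor);
  patches, liquids, and methadone-specific dosing are out of scope.
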