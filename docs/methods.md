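# Methods

This note documents the models, rules and design choices behind
`antithrombo`, in the order the pipeline applies them.

## Study design being modelled

The package implements a new-user (drug-naïve), active-comparator drug
utilisation design over four linked longitudinal tables (patients,
prescriptions, diagnoses, laboratory measurements). Two parallel cohorts are
built: people with an incident indication for anticoagulation (atrial
fibrillation) and people with an incident indication for antiplatelet
therapy (myocardial infarction, peripheral arterial disease, unstable
angina, or transient ischaemic attack). Each cohort is split by prevalent
chronic liver disease, defined as any prior diagnosis of one of six
conditions: alcoholic liver disease, autoimmune liver disease, cirrhosis,
chronic hepatitis B, chronic hepatitis C, or NAFLD. For liver patients only
indications dated *strictly after* the first liver diagnosis qualify:
"diagnosed after" is read strictly, and same-day ties are excluded because
within-day ordering is unknowable at day resolution. A patient may enter
both class cohorts; the two are processed independently.

Follow-up runs from the indication to the earliest of: primary endpoint,
death, last practice data collection, deregistration, or administrative
censoring (default 2020-06-30). Ties on the same calendar date resolve by
that priority order. The age restriction (≥ 30 years) is enforced at the
indication date, the analysis entry point.

All dates are calendar dates; interval arithmetic uses integer day offsets
and half-open `[start, end)` intervals throughout, which removes off-by-one
ambiguity from the supply and gap rules below.

## Prescribing prevalence

Prevalence is the share of drug-naïve cohort members with at least one
same-class prescription on or after the indication date (any time during
follow-up; a fixed post-indication window can be imposed via configuration).
Intervals are Wald (normal-approximation) intervals for a binomial
proportion, p ± z·√(p(1−p)/n), reported per 100 persons, clipped to
[0, 100]. Wilson or exact intervals were deliberately not used: the target
estimator is the central-limit-theorem interval. Degenerate cells (k = 0 or
k = n) are reported with a zero-width interval and flagged. Rounding is
half-up to one decimal and applied only at presentation; internal values
stay exact.

## Supply episodes and PDC adherence

Each prescription issue is assumed to supply 30 days of medication
(`supply_days`, configurable). If the next issue arrives within 30 days the
earlier episode is truncated at the next issue — there is no stockpiling or
carry-over. The last issue always contributes the full assumed supply.
Same-day duplicate issues collapse to one (the truncation rule would
otherwise degenerate to a zero-length episode).

PDC over a window of 183 days (6 months) or 365 days (12 months) from the
first class prescription is covered days divided by window days. A patient
is *adherent* when PDC is strictly above 0.80. Eligibility for the PDC
analyses requires follow-up of at least the window length and more than one
class prescription; a patient with exactly one class prescription is
*primary non-adherent* and is excluded from PDC and persistence analyses.

Drug-level PDC uses the index drug's own issues, and by default stops
accumulating at an in-class switch (`pdc_stop_at_switch`); class-level PDC
uses the union of all class episodes. The interval arithmetic is verified
against a brute-force boolean day-grid oracle in the tests.

## Persistence

A patient is persistent until a prescription gap of 90 days is *reached*
(comparison `>=`). The gap is measured from the end of the assumed supply to
the next issue (or to the end of follow-up when there is no next issue);
measuring from the issue date instead is available via `gap_from="issue"`.
The discontinuation date is the end of the last covered episode —
the standard pharmacoepidemiologic convention.

Switching to a different drug of the same class censors persistence
follow-up at the switch date rather than counting as discontinuation. When
a qualifying gap and a switch fall on the same day, the switch dominates.
Landmark status at 6/12 months is decided by the earliest of
discontinuation, switch and the landmark; landmark denominators include
only patients with at least that much follow-up and exclude primary
non-adherence. The joint adherence × persistence table uses the
landmark-eligible population (including switch-censored patients) as its
denominator, so its four cells plus the censored category partition each
denominator exactly — an invariant asserted in the tests. The
time-to-discontinuation output (`event_time_days`, `event_flag`) feeds the
Cox non-persistence model with switch and follow-up end as censoring.

## Severity and risk scores

*Child-Pugh*: five components scored 1–3 — total bilirubin (<2 / 2–3 / >3
mg/dL), serum albumin (>3.5 / 2.8–3.5 / <2.8 g/dL), INR (<1.7 / 1.7–2.3 /
>2.3), ascites and hepatic encephalopathy (absent / present / severe). The
sum (5–15) maps to class A (5–6), B (7–9), C (10–15). Ascites and
encephalopathy presence comes from the diagnosis stream and scores 2 points
unless a severe grade is flagged; this is an explicit assumption, as coded
severity grading is not available in the condition enumeration. Missing lab
components withhold the score and are named rather than imputed.

*FIB-4*: age × AST / (platelets × √ALT) (the standard Sterling formula,
adopted explicitly since only components and strata are fixed by the
design). Strata: <1.45, [1.45, 3.25] (closed middle band), >3.25.

*CHA₂DS₂-VASc*: standard weights — congestive heart failure 1, hypertension
1, age ≥ 75 2 (65–74 1), diabetes 1, prior stroke/TIA 2, vascular disease 1,
female sex 1 — with strata 0–1 / 2 / 3–4 / 5–9. Myocardial infarction and
peripheral arterial disease count toward the vascular-disease component.

Labs feed the scores through a lookback window: the most recent measurement
within 365 days before or 30 days after the index date (both configurable).
Units are fixed per analyte in the schema, never per row, so a unit mix-up
cannot silently corrupt the scores.

## Rosendaal TTR

Between consecutive INR measurements the INR path is interpolated linearly;
the in-range fraction of an interval equals the fraction of the value
interval intersecting [2.0, 3.0] (inclusive boundaries; for a constant
segment, 1 if in range else 0). TTR is the in-range share of all
interpolated days, in percent. Time before the first and after the last
measurement is excluded. No maximum inter-measurement gap is imposed by
default (`max_gap_days` is available; classic implementations often drop
gaps > 56 days). TTR is undefined with fewer than two in-period
measurements, and such patients are excluded from TTR-stratified models.
The assessment period defaults to the 12-month adherence window from the
index date and is exposed as a parameter. The closed form is verified
against a fine-grained quadrature oracle (exact integration over
10⁻³-day cells) to 10⁻⁶.

## Risk models

Uncovered time — follow-up days not covered by supply episodes — is a fixed
per-patient exposure categorised as <1 week, 1 week–1 month, 1–3 months,
3–6 months, >6 months (left-closed boundaries at 7/30/91/183 days,
calendar-faithful readings of the labels). A time-updated exposure variant
is deliberately out of scope: the target presentation is a single
per-patient category.

* **Non-adherence** at 6/12 months: multivariable logistic regression,
  fully adjusted, among landmark-eligible non-primary-non-adherent
  patients. Reference levels: warfarin (anticoagulants) / aspirin
  (antiplatelets), age 30–49, CHA₂DS₂-VASc 0–1, Child-Pugh A, FIB-4 <1.45.
* **Non-persistence**: Cox proportional hazards on time to discontinuation
  with switch/end-of-follow-up censoring, plus a proportional-hazards
  diagnostic (scaled Schoenfeld residual correlation test against rank
  time, per term).
* **Stroke**: Cox on the uncovered-time category with "<1 week" as
  reference, optionally stratified by CHA₂DS₂-VASc stratum, optionally with
  a liver-status contrast. The adjustment set is configurable.
* **Bleeding**: Cox on PDC scaled per 10 percentage points.

Effects are exponentiated coefficients (OR/HR) with Wald CIs on the log
scale. Covariates with a single observed level are dropped with a warning
(separation guard). Logistic fits use statsmodels; Cox fits and the PH test
use lifelines.

Because the licensed source cohort is out of reach by design, the models
are validated by *parameter recovery* rather than by reproducing published
coefficients: planted hazard ratios (a 1.5 stroke multiplier for >6 months
uncovered; a 1.18 bleeding multiplier per 10% PDC; a 0.5 DOAC-vs-warfarin
odds ratio) must be recovered within ±0.15 of the generating value at
n = 20,000 (5,000 for the logistic), and null simulations must show ≥ 90%
CI coverage over 100 replicates.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not the English
population: person-level linkage; ~30% prevalent liver disease with six
subtype weights proportional to the relative subtype cohort sizes; incident
indications arriving as an exponential waiting time (0.10/year) after the
first liver diagnosis (or after registration for non-liver patients);
class prescribing probabilities of 0.206/0.335 (anticoagulants,
liver/non-liver) and 0.562/0.711 (antiplatelets), matching the prevalences
the analysis is designed around; and death/deregistration censoring at
0.03/year each.

Refill behaviour uses four archetypes rather than a single adherence
distribution so that every cell of the joint adherence × persistence table
is populated by construction: primary non-adherers (one issue, weight
0.06, near the observed 5–8% rates), steady refillers (~Normal(30, 4) day
intervals, weight 0.40), irregular refillers (a 0.65/0.35 mixture of
~Normal(26, 8) and ~Normal(80, 25) intervals, weight 0.30) and early
discontinuers (a Geometric(mean 3) number of refills, weight 0.24). In-class
switching occurs with probability 0.10 at a uniformly chosen refill.

Warfarin users receive an INR series sampled every 14–42 days as a
stationary AR(1) process (mean 2.5, marginal SD 0.5, lag-1 correlation
0.7), which lets tests place TTR above or below the 60% cut deliberately.
Labs sufficient for Child-Pugh and FIB-4 are emitted around the indication
date with liver-status-shifted distributions. Stroke and bleeding event
times are exponential with hazards multiplied by the configured
uncovered-time-category and per-10%-PDC effects; the generator's truth
table records every draw so downstream modules can be checked against the
generating process exactly.

What the generator does **not** emulate: realistic regional geography
(regions are uniform labels), comorbidity correlation structure beyond what
the scoring operations need, dose information, OTC aspirin, re-initiation
after a qualifying gap, and calendar trends in drug choice. Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
planted effects — not epidemiological realism of any particular rate.

## Problem sizes and numerics

The packaged analysis runs at 2,000 simulated patients (a few seconds end
to end); parameter-recovery studies use 20,000 exposure summaries with
event rates raised (base hazards 0.05/year) and allocation weighted toward
the contrasted categories (40/5/5/10/40%) so the planted contrasts are
estimated precisely. These sizes are the package's own choices and are
configurable. Oracle comparisons use exact integer day-grid arithmetic
(PDC) and exact per-cell integration (TTR), so the stated tolerances
(10⁻¹², 10⁻⁶) reflect floating-point noise only. Seeds control every source
of randomness; identical seeds reproduce byte-identical tables.

## Known limitations

Prescriptions carry issue dates only — quantity/duration fields are not
modelled, hence the blanket 30-day supply assumption. The
code-list→condition mapping layer is a declared extension point that ships
empty: real Read/ICD-10 phenotype dictionaries are licensed resources. The
non-liver cohort takes a patient's earliest qualifying indication within
registration rather than restricting to a study-window start. Child-Pugh
severity grading of ascites/encephalopathy from coded data is approximated
by a presence/severe flag.
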