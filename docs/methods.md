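# Methods

## The comparison being made

Two imperfect observers classify the same participant for the same
condition: a longitudinal survey (self-report, carry-forward over
waves) and a coded medical record (rule-based case ascertainment).
Agreement is summarized per condition by positive agreement
PA = 2a/(2a+b+c), negative agreement NA = 2d/(2d+b+c), and Youden's
J = a/(a+c) + d/(b+d) − 1, where (a, b, c, d) cross-classify
(survey, record) status as (+,+), (+,−), (−,+), (−,−).  PA and NA are
the proportion-of-specific-agreement statistics of Cicchetti and
Feinstein: chance-uncorrected agreement restricted to the positive
(or negative) cells, appropriate when neither source is a gold
standard.  J treats the record as the reference for sensitivity and
specificity of self-report; it is prevalence-independent, which the
suite verifies as an exact invariance (scaling the record-positive and
record-negative columns leaves J unchanged).  Cells equal to zero make
a statistic's denominator empty; such statistics are reported as
absent, never coerced to 0, to avoid silent bias for rare conditions.
Pairs with a missing status in either source are excluded before the
table is built, and exclusion counts are carried in the run manifest so
that rows in = rows retained + rows excluded at every stage.

## Record-based ascertainment

Codes are normalized (upper-case, whitespace and decimal point
removed) and matched in any diagnostic position; matching is by prefix
by default — published code lists typically include truncated parent
codes — with an exact mode per code set.  The observation window
defaults to 1999-10-01 through 2020-09-18.  Two criteria are
implemented:

* **sensitive** — one qualifying code on any inpatient or outpatient
  record; diagnosis date = earliest matching encounter/admission date;
* **specific** — one inpatient code, or outpatient codes on at least
  two *distinct* event dates.  The distinct-date reading of "two
  outpatient codes" follows the standard claims-algorithm "rule of
  two" (two codes entered at a single visit do not qualify); it is a
  configurable switch because the alternative (any two code rows) is
  also defensible.  Diagnosis date = earliest qualifying date (the
  admission date or the first of the two outpatient dates).

Specific-positive implies sensitive-positive on the same records, so
the sensitive definition is a superset; the suite checks this, and
checks both criteria against an exhaustive loop-based evaluator on
randomized small record sets.

**Temporal restriction.**  Restricted analyses keep only codes
*strictly* before a per-participant reference date — a same-day code
cannot be shown to precede the survey — and drop personal-history
codes, which carry no date of diagnosis.  The reference date is the
first-yes survey date for survey positives and the last completed
survey date for survey negatives (so negatives face a comparable
look-back; configurable to exclusion).  Survey-missing participants
have no reference date and are excluded from restricted comparisons.

**Source scope.**  Records may be limited to the primary system (VHA;
purchased-care encounters are ingested under it) or pooled with a
second system (MDR).  Merging is disjunctive: positive if either
source is positive, with the earliest diagnosis date.  Prevalence is
therefore monotone in scope, anti-monotone in criterion strictness and
in temporal restriction — all verified across random cohorts.

## Survey classification

A "yes" at any wave classifies the participant positive at that and
all later waves (diagnosis date = survey date at first self-report);
"no" at any wave without a "yes" anywhere classifies them negative;
all-missing is missing.  Baseline asks *ever*, follow-ups ask *in the
past 3 years*; both are treated identically as yes/no evidence because
the classification rule consumes answers, not recall windows.

## Behaviors and body measurements

* **Problem drinking (survey):** endorsement of ≥ 1 of 5 PHQ
  risky-drinking items; all-five-no is "no".  When nothing is endorsed
  and an item is missing the flag is missing (a denial cannot be
  established) — the handling of partial item response is this
  package's decision.  Any-wave endorsement defines the per-participant
  flag (configurable in principle to latest-wave).
* **Alcohol misuse (record):** AUDIT-C ≥ 3 (women) / ≥ 4 (men), taken
  from the assessment closest in time *strictly prior* to the survey
  date; same-day duplicates resolve to the highest score.
* **Ever smoker:** survey — lifetime-100-cigarettes item with
  carry-forward; record — smoking status closest to the survey date on
  *either* side (the prior-only restriction applies to AUDIT-C, not to
  smoking), equidistant ties to the earlier record, status
  current/former ⇒ ever.
* **Anchor date:** record-side behavior assessments are matched to each
  participant's last completed survey date, the wave with the most
  accumulated self-report; which survey anchors the comparison is not
  otherwise determined.
* **Height:** per source, the modal value; frequency ties break to the
  earliest-dated modal value; all-distinct falls back to the first
  recorded.  **Weight:** the measurement closest to the survey date
  within 365 days on either side (inclusive; a one-sided prior-only
  switch exists), equidistant ties to the earlier, pre-survey
  measurement.  Weights < 80 or > 500 lb and heights < 48 or > 95 in
  are removed first (strict inequalities; boundary values kept).
* **Bland–Altman:** differences are record − survey; SD uses the n−1
  denominator; limits are mean ± exactly 2 SD (not 1.96); the
  proportion outside counts pairs strictly beyond the limits.  Weight
  summaries are emitted per survey year.

## Utilization categories

Per participant, over distinct VHA encounter dates up to the cutoff:
high-frequency = more than one encounter in every observation year;
regular = at least one per year on average; irregular = fewer than one
per year on average but at least one encounter.  The observation period
runs from first to last encounter, in 365.25-day years, floored at one
year so single-visit participants are classifiable (a single visit then
averages exactly one per year: regular).  "Every year" is evaluated
over consecutive 365.25-day intervals anchored at the first encounter,
which avoids calendar-year artifacts; a final partial interval imposes
the requirement only when it spans at least half a year, and
high-frequency additionally requires the average to exceed one per
year, which keeps high-frequency a subset of regular even for
degenerate spans.  Within a fixed span, adding an encounter never
lowers the category (property-tested); an added encounter that
*extends* the span can legitimately break the every-year requirement,
which is inherent to the definition rather than an implementation
artifact.

## The synthetic cohort generator

The generator exists to give the pipeline a cohort whose correct
answers are known.  Each participant draws a latent true status per
condition; each of the two channels then draws **one** Bernoulli
outcome per participant-condition — positive with probability equal to
the channel's sensitivity given a true case, or one minus its
specificity otherwise.  Channels are conditionally independent given
truth (a shared-error probability above 0 couples them comonotonically;
default 0), so the expected cell probabilities are closed-form, e.g.
P(both+) = p·s₁·s₂ + (1−p)(1−c₁)(1−c₂), and `expected_agreement` maps
them through the same PA/NA/J formulas used on counts.

Observable data are then materialized consistently with the channel
outcomes: a survey-channel-positive participant first reports at a
uniformly chosen completed wave and at every completed wave after; a
record-channel-positive one receives coded encounters (at least one;
mean per true case configurable, one stray miscoded visit for false
positives) on uniform dates in the window, split across sources and
settings by the configured fractions.  Background encounters arrive as
a Poisson process (default one per person-year) carrying a
non-matching code.  Wave nonresponse (default completion probability
0.7 per wave over five waves dated 2001–2014) is independent of truth,
so dropping missing pairs leaves the closed form exact; an item-level
missingness knob exists but defaults to 0 because item missingness
correlated with the answer pattern would bias the channel
probabilities.  Heights and weights come from sex-specific normals
with a configured self-report bias (default +0.5 in and −6 lb with
reporting noise, so records read shorter and heavier than self-report);
AUDIT-C scores and smoking statuses are drawn around latent misuse and
smoking indicators.  Each table uses its own random stream spawned from
the master seed, so adding a table leaves the others byte-identical.

What the generator does **not** emulate: ICD code hierarchies and
miscoding into related codes, comorbidity correlation between
conditions, care-seeking that depends on disease severity, survey
nonresponse correlated with health, drift of weight over time, or
panel sampling weights.  Passing tests on synthetic cohorts therefore
demonstrates that the pipeline's logic and algebra are correct under
the stated observation model — not that any particular real cohort
meets that model's assumptions.

## Validation against published tables

Without the restricted participant-level data, published cohort
results cannot be recomputed directly.  What *can* be checked is
internal consistency: given a printed row's N, its two positive
margins, and its positive agreement printed at one decimal, the solver
enumerates every integer dual-positive count a whose exact PA rounds
(half-up, matching table formatting) to the printed value, fills
b, c, d from the margins, and recomputes NA and J.  For the reference
rows used in the tests the reconstructed NA and J match the printed
values at printed precision; for most rows every consistent a yields
the same rounded NA and J, and where the candidate set straddles a
rounding boundary the modal rounded value (frequency ties resolved to
the median candidate) is reported.  Cohort-dependent quantities whose
inputs are unprinted — behavior-table denominators, Bland–Altman means
— are explicitly not reconstructable and are not reported.

## Problem sizes and numerical choices

The suite exercises parameter recovery on one 100,000-participant
cohort (every condition's PA, NA, and J within three binomial standard
errors of the closed form, with the standard error of J combining the
two margin-level variances) and monotonicity on one hundred
1,000-participant cohorts; randomized cross-checks against brute-force
evaluators use a few hundred draws each.  These sizes make Monte-Carlo
noise small relative to the tolerances being asserted while keeping a
full run of the suite inexpensive.  All randomness flows from explicit
integer seeds; printed-table comparisons round half-up at printed
precision (one decimal for percentages, two for J); statistics with
empty denominators propagate as absent values end to end.

## Known limitations

* The closed-form oracle applies to the sensitive-criterion, any-time,
  combined-source configuration; under specific criteria or temporal
  restriction the generator's observed agreement depends on encounter
  placement, and those configurations are validated by inequality and
  equivalence properties instead.
* Condition columns and the behavior items enter the survey table in
  the generator's fixed wide format; free-format survey instruments
  must be mapped to it by the caller.
* The utilization classifier loops per participant and is intended for
  stratified reporting, not for million-participant hot paths.
* Agreement statistics are reported without confidence intervals, and
  kappa-type chance-corrected statistics are out of scope.
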