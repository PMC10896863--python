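# Methods

This note documents the measurement procedure, the synthetic-data model,
the numerical conventions, and the design choices made where the design
was genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Day-level exposure construction

All measurement happens on a 1-based day grid: the index fill date is day
1 and follow-up runs through day `followup_days` (default 365).  Claims
carry calendar dates everywhere else; the conversion to day indices
happens only in `artgaps.exposure`, so off-by-one conventions live in one
place.  A fill on day *d* with *s* days' supply covers days *d..d+s−1*
when nothing intervenes.

Two adjustments modify that baseline:

* **Same-drug carry-over.**  Per drug, a pointer tracks the day after the
  last supplied day; a fill's adjusted start is `max(fill day, pointer)`.
  An early refill therefore queues behind the current supply (fill on day
  1 with 30 days, refill on day 28 → adjusted start day 31).  There is no
  carry-over across distinct drugs: coverage is the union over all anchor
  agents ("any anchor" adherence), so switching is not penalized, and
  overlapping supplies of different drugs cover their overlap days once.
  Multiple same-drug fills on one day have their supplies summed before
  adjustment.
* **Facility-stay stockpiling.**  Days in a hospital / skilled nursing
  facility / hospice are excluded from both numerator and denominator.
  A stay day is always classed `facility`, never `covered`, and supply is
  conserved: consumption skips stay days and resumes after the (merged)
  stay ends.  A fill whose adjusted start lands inside a stay starts the
  day after the stay ends — the conservation rule generalizes that
  special case to stays that begin mid-supply.  Adjacent or overlapping
  stays are merged before any of this.

Supply extending past the window end is truncated for measurement, but
the per-drug pointer advances logically beyond it.  Pre-index fills
contribute nothing by default: the index drug has none inside the washout
by construction, and a continuing background anchor's tail supply is
treated as belonging to the pre-period regimen (set
`include_preindex_anchor_tail` to count it — a sensitivity flag, not the
default, because the initiation being measured starts at index).

The engine computes with merged day intervals rather than a per-day loop.
The test suite checks it for exact agreement, on every day of more than a
thousand simulated people plus randomized small cases, against a
deliberately naive oracle that walks the calendar day by day holding one
remaining-supply counter per drug.

## Outcomes

* **PDC** = covered days / (window − facility days), kept as an exact
  rational number.  Threshold flags and the optimal (≥ 0.95) /
  intermediate (0.70–0.95) / low (< 0.70) categories compare the exact
  ratio against the thresholds read as decimal literals; rounding happens
  only at presentation.  This matters at the optimal boundary, where
  0.95 × 365 = 346.75: 347/365 is optimal, 346/365 is not.  A person
  whose whole window is facility time has undefined PDC and is excluded
  from adherence summaries.
* **Gap runs.**  Under the default `bridge` policy a run is a maximal
  stretch of non-covered days containing at least one gap day; facility
  days inside it bridge the run but add nothing to its length, and the
  run's start/end are trimmed to its first/last gap day.  Under `split`
  a facility day terminates the run.  The text this methodology follows
  does not resolve the choice; `bridge` is the default, the policy is
  configurable, and summaries record only lengths consistent with the
  chosen policy.
* **Discontinuation** = some run with ≥ `discontinuation_gap_days`
  (default 90) gap days fully observed inside the window — no
  extrapolation past day 365, which the cohort's guaranteed complete
  follow-up makes well-defined.  Time to discontinuation is
  `start_day − 1` of the first qualifying run: a 30-day index supply
  never refilled gives a gap starting day 31 and a time of 30 days.
  With defaults, times lie in [1, 275].
* The longest gap is binned into "0 days (no gap)", 1–6, 7–<14, 14–<30,
  30–<90, 90–<120, 120–<150, 150–<180, ≥180 days.  "Any gap" is reported
  at both the ≥1-day and ≥7-day definitions, labelled, since either
  reading of "at least one gap" is defensible.

## Cohort selection

An index event is the first in-window fill of an anchor drug not filled
in the preceding `pre_period_days` (365).  Choices made where the
operational text is silent: the washout is 12 months (not all available
history); among multiple qualifying initiations the earliest wins (the
standard new-user convention); switchers are not required to have
discontinued the prior anchor; "multiple anchor medications on the index
date" means more than one distinct *qualifying new* anchor drug id that
day — a same-day refill of a background or non-anchor agent does not
trigger the exclusion.

Continuous enrollment is evaluated at month granularity, mirroring
monthly summary-file indicators: every calendar month touching
[index − 365, index + 364] must carry the joint A/B/D flag; partial
months at the boundaries count as required months (our convention — the
source methodology does not state one).  The pre-index HIV-diagnosis
window is [index − 365, index − 1]; codes are compared case-insensitively
with decimal points removed.  The attrition table records the count
remaining after each criterion, and selection is invariant to input row
order.

## Synthetic claims generator

The generator emulates the data structures the analysis assumes, not any
real population's joint distribution.  Demographic fields are sampled
independently from published margins of the study population (so
age–eligibility correlations, for instance, are absent by design); the
comorbidity flags, HCC risk score (lognormal matched to mean 1.04, SD
0.92), and pre-period prescriptions per month (gamma, mean 6.10, SD 4.37)
are likewise marginal.

Refill behaviour is cycle-based: at each nominal supply exhaustion the
person (1) stops permanently with the per-cycle hazard (default 0.01,
chosen so that ~10% of a cohort discontinues within 12 months of 30-day
cycles, the order of magnitude reported for Medicare ART users); else
(2) switches to another anchor agent with probability 0.02; then
(3) refills on time — uniformly 0–7 days *early*, probability 0.8 — or
late with a geometric delay of mean 7 days.  Covariate effects enter only
through the per-cycle stop hazard (log-odds shift) and the mean delay
(log-scale multiplier): the smallest mechanism that makes the association
models' estimands recoverable.  Facility stays are sampled independently
of refill behaviour (0.4 stays/person-year, geometric mean duration 6
days), deaths occur in follow-up with annual probability 0.04, and half
of beneficiaries are treatment-experienced switchers with a prior anchor
filled monthly from before the index window through the pre-period.  The
cycle design gives closed-form expectations for tests — with zero delay
there are exactly 13 fills and 13 stop decisions in 365 days, so the
stopping fraction is 1 − (1−h)^13.

One RNG stream per beneficiary is derived from (seed, beneficiary index),
so identical parameters give byte-identical bundles and enlarging a
cohort never perturbs existing people.  A ground-truth side table (true
stop day, first switch day, per-person stop probability and delay mean)
supports recovery tests, and `inject_scenario` adds fully specified
edge-case beneficiaries (death in follow-up, enrollment break, dual
anchor index, fill during stay, stay mid-supply, early refill) with a
marker table naming them.

What passing tests therefore show: the measurement and modelling
machinery is correct on data with the assumed structure, and planted
effects are recovered at realistic sizes.  What they do not show:
anything about real claims' joint covariate distributions, seasonal or
benefit-phase refill patterns, data-quality artifacts (reversed claims,
duplicate NDC variants), or transfers between payers.

## Models

The analysis table joins outcomes to covariates: age band at index
(≤34 … ≥85; computed with a 365.25-day year, so 64.9 years falls in
55–64), sex, race/ethnicity, low-income-subsidy status, eligibility
reason, census region, metropolitan status, plan type, index year, index
anchor class × single-/multi-tablet status (PIs form one level — no PI
single-tablet products existed in the study window), HCC score,
comorbidity flags, and pre-period prescriptions per month.

Fitting is routine maximum likelihood (statsmodels `MNLogit`/`Logit`,
lifelines `CoxPHFitter`); this package pins the conventions: optimal
adherence is the multinomial reference outcome; reference covariate
levels are never emitted; confidence intervals and p-values are Wald;
ties in the Cox model use Efron's method; non-discontinuers are
administratively censored at day 365 (deaths cannot occur in-cohort by
construction); no multiple-testing adjustment.  Degenerate inputs —
a single observed outcome category, an all-event or all-censored
outcome, an unobserved reference level, non-convergence or
quasi-separation (detected as a diverging coefficient) — raise a
structured `ModelFitError` naming the model and, where identifiable, the
offending term.

Sparse strata: categorical levels or binary flags observed fewer than
`min_level_count` times are merged into the reference / dropped before
fitting and listed in the completeness report.  The library default is 0
(off); the CLI uses 25 so that demo-scale runs (a few hundred people)
fit the full covariate list stably.

## Problem sizes and seeds

Defaults were chosen once, as study conditions, before results were
read: demo pipeline n = 500; oracle-equivalence comparison on ~1,100
simulated people; invariant suites on two seeds at n = 400; planted-effect
recovery on 20 replicates of n = 5,000 with a planted per-cycle odds
ratio of 1.5 on a 30%-prevalence flag.  All randomness flows from
explicit integer seeds through per-person substreams.

## Known limitations

* The bridge/split ambiguity for facility days inside a gap is resolved
  by configuration, not evidence.
* The generator's nominal-exhaustion refill clock ignores accumulated
  stockpile when timing the next refill; early-refill drift therefore
  produces slightly more fills than a stockpile-aware pharmacy would.
* Eligibility breaks arise in the generator only via scenario injection,
  so the enrollment criterion is exercised by fixtures rather than by the
  stochastic model.
* Quantity (pills dispensed) is carried but unused: adherence is
  days'-supply-based, with no dose-level resolution.
* No multi-year follow-up, no restart detection after a ≥90-day gap, and
  no linkage to clinical outcomes.
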