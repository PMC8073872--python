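# Methods

This package implements a trial-based, lifetime cost-utility analysis of
self-managed computerised word-finding therapy added to usual care for
chronic post-stroke aphasia, compared with usual care alone and with an
attention control (puzzle books plus monthly calls) added to usual care.
This note records the model, its assumptions, the tunable parameters, and
the design decisions taken where the published description of such
analyses leaves the design open.

## The decision model

A Markov cohort model with five health states:

* **Aphasia** — the starting state; everyone begins here.
* **Good response (6 months)** and **Good response (9 months)** — tunnel
  states occupied for exactly one 3-month cycle, indexing time since
  response so that relapse probabilities can differ by assessment
  interval.
* **Good response (12 months and beyond)** — absorbing on the response
  side; occupants either stay, relapse to Aphasia, or die.
* **Dead** — absorbing.

Cycles are 3 months. Response transitions occur only at the
assessment-aligned cycles (months 6, 9 and 12), because those are the
time points at which trial outcome data exist; death can occur from any
state in every cycle. After month 12 no new responses occur: the relapse
probability observed across the 9→12-month interval (one cycle) is
carried forward unchanged for the rest of the horizon. New responders at
9 and 12 months are permitted among prior non-responders and enter the
corresponding tunnel state alongside maintainers.

A **good response** is a gain from baseline of ≥ 10 words on a 100-word
personalised naming test *or* ≥ 0.5 points on the Therapy Outcome
Measures activity scale (an OR rule; both thresholds configurable).

**Mortality** is identical across states and arms — the interventions are
assumed not to affect survival — so modelled life expectancy is
arm-invariant by construction (asserted in tests). An annual death
probability q(age) from a life table is combined with a post-stroke
hazard multiplier m on the hazard scale (h = −ln(1−q), q* = 1−e^(−mh)),
which stays a valid probability for any m > 0, then converted to a
3-month probability 1−(1−q*)^(1/4). The multiplier form (rather than
absolute post-stroke rates) is a design choice; the default m = 1.7 is a
synthetic convention supplied in config.

**QALYs** accrue per cycle as occupancy × state utility × ¼ year (three
months at utility 0.8 yields 0.2 QALYs) and are discounted at 3.5% per
year, applied at cycle end with elapsed time t = cycle × 0.25 years.
Good-response state utilities are u_aphasia + δ(assessment), with the
increment added *before* the multiplicative ageing decrement. The ageing
decrement is a per-age index supplied as data (default flat 1.0; a
linear-decline helper is provided); utilities age in annual steps.
Half-cycle correction is off by default, matching the accrual rule
above, and available as a flag. **Costs** are one-off year-1 intervention
costs and are not discounted; usual-care costs are excluded because usual
care continues in every arm and cancels from every incremental
comparison.

The horizon runs from the cohort start age (default 65) to a terminal
age of 100 plus one year of cycles; the life table forces q = 1 at the
terminal age, so the cohort is always fully absorbed. An early stop
triggers when living occupancy falls below 1e-8.

The cohort engine is vectorised over parameter draws (a deterministic
run is the one-draw special case) and is cross-checked against an
individual-level microsimulation of the same transition rules, kept as
an independent sampling-based implementation.

## Utilities and value sets

EQ-5D profiles (five dimensions, 3 or 5 levels) are scored by pluggable
value sets: a full lookup table (243 or 3125 states) or an additive
coefficient scheme (any-problem constant, per-dimension per-level
decrements, optional worst-level term). Published tariffs and crosswalks
are *consumed* as data files, never embedded: the value sets shipped here
are synthetic, built so the 3L-style set's worst state scores exactly
−0.594 (the conventional floor of that scale) and the 5L set's 3125
states spread densely over the scale. Secondary analyses that re-score
the same profiles under a different tariff are just a different
`ValueSet` argument; the proxy-report secondary analysis re-scores the
carer-completed profiles.

The Good-response utility increment at each assessment is the difference
in mean change-from-baseline utility between responders and
non-responders (unadjusted; whether any covariate adjustment should be
applied is left to the caller, and the estimate is invariant to constant
shifts in the utility scale). The Aphasia-state utility is the pooled
baseline mean — it must come from data or config; the package hard-codes
no value.

## Probabilistic analysis

All uncertain inputs get conventional distributions: **beta** for
transition probabilities, parameterised directly by events and
non-events from the estimation counts (boundary counts of 0 collapse to
a point mass, since α, β must be positive); **normal** for utility
increments (mean, SE); **gamma** for costs, by method of moments from
mean and SE. Draws are independent across parameters (correlation is not
modelled — a documented limitation); the post-12-month relapse shares
the 9→12 relapse draw because it is the same parameter carried forward.
All arms see the same draw of shared parameters in an iteration, so
increments difference out shared noise.

The default run is 10,000 iterations. Mean incremental costs and QALYs
over draws give the best-estimate ICER; 95% credible intervals are
percentile-based (2.5th/97.5th). Dominance labelling: ΔC > 0, ΔQ < 0 is
"dominated"; ΔC ≤ 0, ΔQ > 0 is "dominant" (including the cost-free
gain); ΔC < 0, ΔQ < 0 is reported as a labelled southwest quadrant
rather than a misleading ratio; ΔQ = 0 is undefined, never a division
error. CEACs use net monetary benefit λQ − C on a £0–£100,000 grid in
£500 steps (so £20,000 and £30,000 are always included); exact NMB ties
split an iteration's probability mass evenly. A zero-variance mode
collapses every distribution to its mean and reproduces the
deterministic run to full floating-point precision (the scalar and
vector engines accumulate in the same order to make this exact).

RNG: each PSA run derives all draws from one `numpy` generator seeded
from the run seed; per-imputation blocks offset the seed. This replaces
a per-iteration substream design — with a fully vectorised engine the
practical reproducibility contract (identical results for identical
seeds, independence of unrelated code paths) is met at much lower cost.

## Missing data

Missing utility and outcome scores are imputed by predictive mean
matching: fit a linear model on complete cases, draw σ² and β from their
sampling distributions (proper imputation; a toggle fixes them for
deterministic tests), predict for all records, and fill each missing
value with the observed value of one of the k nearest-prediction donors
chosen at random. Imputed values therefore always lie in the observed
support. Defaults m = 20, k = 5, predictors = arm, age, baseline naming
score (and baseline utility once imputed), targets chained in time order
— conventional MI practice, chosen here as package defaults, not trial
facts. Downstream estimates pool with the standard combination rules
(mean of estimates; within-variance + (1 + 1/m) × between-variance).
Cost variables are never imputed (the trial reported none missing).

Two execution modes connect imputation to the probabilistic analysis:
the default runs the PSA within each imputed dataset (iteration budget
split evenly, draws concatenated), so imputation uncertainty propagates
into credible intervals; the pooled mode averages the per-imputation
estimates first (widening increment SEs by the between-imputation
variance) and runs a single PSA.

## Costing

Per-participant micro-costing from activity logs at 2016/17 national
unit costs: band-7 SLT training at £0.90/min, band-6 SLT delivery at
£0.75/min, band-5 attention-control calls at £0.57/min, band-3 assistant
time at £0.41/min, travel at £0.45/mile, laptop loan £69 (a £690
purchase amortised over 10 users), headsets £14.50, puzzle books £2.50,
and software licensed per scheme (individual £250 by default; clinician
and 5-licence bundles shared across a configured user count — the
allocation rule is a package assumption). The halved-staff scenario
multiplies the four per-minute staff rates by 0.5 and touches nothing
else, so scenario cost = base − ½ × staff-time component exactly.
Arithmetic is double-precision with half-even rounding to pence at
reporting boundaries; at these magnitudes that is exact to well below
reporting precision.

## The synthetic-data generator

No participant-level data from the underlying trial is public, so the
generator produces trials with the statistical structure the analysis
needs, and its defaults are the study conditions: three arms of 93
participants (≈ 278 total), baseline age N(65, 10), CAT naming scores
in the 5–43/48 eligibility window, EQ-5D missingness rising 1% → 18%
from baseline to 12 months, mean band-6 delivery time 7.13 h so the
expected therapy cost is ≈ £733 (≈ 44% of it SLT time), attention
control ≈ £38, and true utility increments −0.04/−0.02/+0.02 at 6/9/12
months. Quantities the published record does not state are one-time
synthetic conventions, documented as such: response probabilities
(0.45/0.15/0.10 therapy, 0.20/0.10/0.08 controls at 6/9/12 months),
relapse probabilities (0.06/0.04 therapy, 0.11/0.07 controls — low,
because sustained response is what makes a lifetime QALY gain of order
0.02 attainable at a 12-month increment of 0.02), baseline utility mean
0.58 (SD 0.20), the post-stroke mortality multiplier 1.7, the
Gompertz-style life table (q = 0.032·e^(0.09·(age−65)), capped at 1),
and tertile-style severity cut-offs on the baseline CAT score (severe
5–17, moderate 18–30, mild 31–43) — the trial's own subgroup cut-offs
are not public and these defaults are never presented as its
definition.

Outcome scores are constructed to be exactly consistent with the latent
responder state under the OR rule (scores are bounded away from
instrument edges so clipping can never flip a classification), which
makes classification a lossless recovery of the truth — a deliberate
generator property used by the estimator tests. EQ-5D profiles are the
nearest-scoring state to a latent target utility (baseline + increment
+ noise), so expected scored utility matches the configured process up
to quantisation, which the dense synthetic 5L set keeps small. Proxy
profiles worsen each dimension by one level with probability 0.35, so
proxy-scored analyses produce systematically lower utilities.
Missingness is MAR via a logistic model on arm and observed baseline
utility, with the intercept solved numerically so the marginal rate hits
the configured target; baseline utility's own missingness depends only
on arm (it cannot depend on itself).

What the generator does **not** emulate: real covariate distributions
and correlations from the trial, item-level EQ-5D response behaviour,
informative (MNAR) missingness, within-participant serial correlation
beyond the response process, or usual-care resource use. Passing tests
therefore demonstrate that the estimation-to-decision machinery is
correct under the assumed data-generating process, not that the
synthetic trial reproduces the real trial's data.

## Problem sizes and numerical choices

Tests run the cohort model at full lifetime horizons (~145 cycles),
recovery checks at 5,000 per arm, the microsimulation oracle at
100,000 individuals, and PSA coherence at 10,000 iterations; the
pipeline tests use smaller trials (60/arm) and iteration counts (300)
as unit-scale smoke sizes. The acceptance script runs the full pipeline
at 93/arm with 10,000 iterations. Row-stochasticity is enforced to
1e-9 per cycle and verified to 1e-10 in tests; CEAC shares sum to 1
within 1e-12 after tie-splitting; NMB ties are detected at an absolute
1e-9.

## Known limitations

* Parameter correlation in the PSA is not modelled (independent draws).
* No half-cycle-corrected published comparator; the flag exists but the
  default accrual is start-of-cycle occupancy.
* The unadjusted difference-of-mean-changes increment estimator ignores
  covariates; with randomised arms and MAR handled by imputation this is
  unbiased but not minimum-variance.
* Severity subgroup cut-offs, response/relapse probabilities, baseline
  utility and the mortality construction are synthetic conventions
  (above); headline numbers produced from generated data therefore
  characterise the method, not the underlying trial.
* At the realistic sample size (93/arm) the incremental-QALY estimate is
  extremely noisy relative to its magnitude — ICERs computed from a
  single synthetic trial swing widely across seeds. This mirrors the
  genuine uncertainty the method is designed to expose, and it is why
  the acceptance script also reports the deterministic benchmark at the
  generator's true parameters.
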