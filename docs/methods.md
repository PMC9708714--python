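# Methods

## Model structure

The model is a closed-cohort, discrete-time Markov state-transition model
with three states: stable heart failure, hospitalized, and dead. The cycle
length is one month and the default horizon is 240 cycles (20 years) from a
start age of 67, chosen because HFrEF carries high monthly event rates and a
short cycle keeps the discretization error of competing transitions small.
Hospitalization is a transitional state: an admission lasts at most one
cycle, survivors return to the stable state at the next boundary, and each
entry counts as one admission event carrying one per-admission cost.
Recurrent admissions are allowed. Death is absorbing.

Background (non-cardiovascular) mortality is an age-banded monthly
probability (0.00082 at 67–69 rising to 0.00822 at 85+). The cohort's age is
deterministic (start + k/12 at cycle k); ages beyond the last band reuse the
last band's value. Cardiovascular and background death probabilities are
combined **additively**, with the stay probability taking the remainder and a
validation error (never silent clipping) if exits exceed one. A hazard-scale
combination `1 − (1−p_cv)(1−p_ncv)` is available behind the
`mortality_combination="rate"` switch; at these magnitudes the two differ by
less than 1e−4 per cycle.

## Inputs

All inputs ship as a built-in fixture (`base_case_parameters()`) and
round-trip through a flat YAML config. Monthly transition probabilities
(empagliflozin / standard arm): stable→hospitalized 0.01449 / 0.02171,
stable→CV-death 0.00624 / 0.00657, hospitalized→CV-death 0.03865 / 0.04392.
Monthly treatment costs $55.07 / $35.11; per-admission cost $1,408.13
(local-data range $974.20–$3,243.21, deliberately stored asymmetric); annual
utilities 0.871 (stable) and 0.215 (hospitalized); discount rate 5%/year
(one-way range 1–8%); willingness-to-pay thresholds $11,981 and $35,943
(1× and 3× per-capita GDP). Currency conversion (6.373 CNY/USD) is provided
as a utility; stored values are already USD and are never double-converted.

Probabilities are stored at monthly resolution exactly as published rather
than re-derived from trial counts (the counts are not public); the
`trial` module covers that estimation pathway with synthetic data instead.

## Accrual conventions

Where a published cohort model leaves its spreadsheet conventions unstated,
this package fixes them as follows and documents the consequences:

- **Half-cycle correction**: payoffs in cycle k use the average of the
  start- and end-of-cycle occupancy (trace-correction method). Admission
  event costs are attached to entries, not occupancy, and are not corrected.
- **Discounting**: the annual rate d gives a mid-cycle factor
  `(1+d)^(−(k−0.5)/12)`, pairing the time of discounting with the time of
  accrual. With d = 0 the discounted and undiscounted streams are identical
  (tested exactly).
- **Treatment cost** accrues in both alive states: therapy continues during
  an admission month.
- **Horizon**: 240 cycles by default; the termination age implied by the
  age bands (86–87) differs by a year from the 20-year horizon, and the
  horizon is an explicit config knob (`econ.n_cycles`) rather than a silent
  choice.

A systematic scan of alternative conventions (start/mid/end-of-cycle
accrual × start/mid/end/annual-step discounting) moves the base-case ICER
by only about ±1%, so reported agreement with published figures is robust to
this choice, but no consistent convention reproduces every published scenario
figure; see Limitations.

## Summaries

Per-arm outputs are total discounted cost and QALYs, undiscounted life
years, an interpolated median survival (first crossing of the alive fraction
below 0.5; `inf` when not reached), and cumulative incidences. Two admission
summaries are exposed because the field uses both:

- `cumulative_incidence(trace, "hospitalization", k)`: admissions per
  initial cohort member (depleted by death; can exceed 100%), with a
  `first_hospitalization` variant;
- `hospitalization_rate_at_risk(trace, k)`: admissions per stable
  person-month scaled to k months — the recurrent-event "rate" convention
  produced when trial event totals are divided by randomized patients over a
  fixed follow-up. With a constant hazard this equals k × the monthly
  probability, which is how the published 16-month validation percentages
  behave; the acceptance script therefore reports this convention for the
  16-month admission figures.

## Incremental analysis

The ICER is always computed from full-precision totals (the published
two-decimal increments do not reproduce the published ratio under naive
division — a rounding artifact, not a model feature; the exporters round
only for display). Quadrant handling: numeric ICER when the increments share
a sign, `dominant`/`dominated` labels otherwise, and `icer=None` whenever
ΔE = 0 (the undefined-ICER signal). Cost-effectiveness at threshold λ is
dominance or ICER ≤ λ; the per-iteration PSA decision uses the equivalent
but sign-safe net-monetary-benefit rule λ·ΔE − ΔC > 0.

`population_impact` linearly scales per-patient incidence differences
(percentage points) to a patient population; it returns exact products and
does not attempt to match any externally rounded billion-dollar figure.

## Sensitivity analysis

- **One-way / tornado**: each registered input is set to the ends of its
  declared range (±10% of mean for transition probabilities, ±20% for
  treatment costs, the published local range for the admission cost, the
  published 95% CI for utilities, 1–8% for discount), one at a time and one
  arm at a time. Entries sort by ICER span, ties broken lexicographically.
- **Scenarios**: drug-price reductions (the drug component is the
  intervention-arm minus comparator-arm monthly cost, $19.96), per-admission
  costs by hospital level, and horizons of 10/15/20/25 years. The ICER is
  affine in the price-reduction fraction (ΔE is unaffected and ΔC is linear
  in it), which the tests verify to numerical precision.
- **PSA**: 1,000 iterations by default. Each uncertain parameter is drawn
  independently — Beta on probabilities and on annual-scale utilities
  (moment-matched to the published sd, including the 0.215 ± 0.174
  hospitalized utility), Gamma on costs; the discount rate, horizon and age
  table are fixed. Independence is a stated limitation (no correlation
  structure was published). A draw that violates a joint invariant (in
  practice only `u_hosp > u_stable`, a few-per-thousand event) is rejected
  and redrawn, and the redraw count is reported. A single seeded
  `numpy.random.Generator` drives all draws in a fixed parameter order, so
  results are bit-reproducible given the seed; an sd of zero degenerates to
  a point mass at the mean.

## Synthetic trial generator

`simulate_trial` emulates the structure of a two-arm HFrEF trial
(≈1,863/1,867 patients, 16-month follow-up): patient-level monthly state
transitions under the same probabilities as the cohort engine, enrollment
ages Normal(67, 10) truncated to [40, 90] feeding the age-banded background
mortality, recurrent admissions, CV/non-CV death causes, censoring at
follow-up. `estimate_transitions` recovers per-cycle probabilities as events
over person-cycles at risk in the source state, with Wilson score 95%
intervals, and is consistent (coverage ≥ 90% across 100 replications at
n = 50,000 is asserted in the test suite).

The generator matches the model's discrete monthly grid by design, so
recovery tests validate the estimator's bookkeeping, not the model's fit to
continuous-time reality. It does not emulate covariates, informative
censoring, treatment discontinuation, or the published hazard ratios; real
trial data would also not satisfy the constant-hazard assumption exactly.

## Problem sizes and determinism

The deterministic base case is 240 cycles × 2 arms (milliseconds). The test
suite's heaviest jobs are the 1,000-iteration PSA (a few seconds) and the
100 × 50,000-patient recovery study (well under a minute). All stochastic
code takes an explicit integer seed; the CLI refuses a PSA without one.

## Known limitations

- Three states only: no NYHA-class granularity, no post-discharge tunnel
  states, no adverse-event states (their costs are folded into the admission
  cost), no treatment waning or non-adherence.
- Published scenario figures for the 10- and 15-year horizons and for the
  near-zero ministerial-hospital ICER disagree with this implementation by
  more than 5% under every accrual/discount convention scanned; the
  remaining published figures (base case, validation summaries, the other
  ten scenario ICERs, CEAC probabilities) are reproduced within the stated
  tolerances. The corresponding reproduction test is left failing rather
  than loosened.
- PSA samples parameters independently; correlated draws (e.g. between the
  two arms' mortalities) would widen or narrow the CEAC.
- The cohort is homogeneous at baseline; age is the only time-varying
  attribute.
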