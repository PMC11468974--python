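# Methods

## Model structure and assumptions

`stepcea` implements a deterministic Markov cohort model over twelve
mutually exclusive health states: the cross of {healthy, diabetes,
hypertension} with three physical-activity (PA) levels {inactive, low,
moderate-to-high}, plus two chronic complication states (cardiovascular
disease for diabetes, stroke for hypertension) and an absorbing dead
state. Structural assumptions:

- **No comorbidity.** A cohort member holds at most one of the two
  diseases; diabetes states have no transition into hypertension states
  and vice versa.
- **Complications are chronic and terminal-stage.** The only exits from
  a complication state are the self-loop and death; complication states
  carry no PA level and are costed entirely as inpatient care.
- **Complications arise only through the disease state.** There is no
  direct healthy → complication transition; this was a genuinely open
  structural choice and the conservative reading was taken.
- **Closed cohort.** No entrants after cycle 0; the cohort size is
  registrants × tracker-completion fraction (1.7M × 0.385 = 654,500 by
  default).

### Within-cycle event order

Each one-year cycle composes three row-stochastic factor matrices in a
fixed, documented order: (1) PA-level shift, (2) disease/complication
onset, (3) death. The order is a modeling convention (nothing in the
data pins it down); fixing it makes the individual-level oracle
simulation well-defined and exactly comparable. Because each factor is
row-stochastic with dead absorbing, the composed matrix is
row-stochastic with dead absorbing by construction — no renormalization
is ever applied, and an onset row whose probabilities would exceed 1 is
an error, never a silent clip.

### Rates, relative risks, calibration

Inputs are annual rates (events per person-year). Relative risks act
multiplicatively on the **rate** scale and rates convert to one-cycle
probabilities by the constant-hazard map p = 1 − exp(−rate·cycle), which
keeps probabilities in [0,1) for any nonnegative RR. Published inputs
are population-average rates, so each is calibrated to an
inactive-reference rate i₀ by prevalence weighting (Σₖ πₖ RRₖ i₀ =
i_observed); the per-level rate is then RRₖ i₀. This calibration is
applied to:

- disease incidence, using the healthy group's baseline PA mix;
- complication incidence, using the parent disease group's PA mix and
  the same incidence RRs — increased activity is assumed to protect
  against disease progression as well as onset, which is what lets the
  prevalent diseased pool (the majority of complication flow over a
  10-year horizon) benefit from the program;
- all-cause mortality, using the cohort-wide baseline PA mix
  (disease-prevalence-weighted). Within every living group the inactive
  RR is exactly 1, so uncomplicated disease carries no excess mortality
  of its own; excess death risk enters through the complication states,
  whose mortality is the census rate times a per-state multiplier.

### Aging

Age bands are 5-year bands from 17–19 to 85+ (3 coarse bands at toy
scale). Each cycle a fraction 1/width of a band's occupancy advances to
the next band — the deterministic expected flow of a population aging
one year inside multi-year bands. The microsimulation oracle advances
individuals with Bernoulli(1/width) draws, whose expectation equals the
cohort flow exactly, so the two implementations are comparable without
any per-age bookkeeping.

### Outcomes, discounting, perspectives

Costs and QALYs accrue with half-cycle correction: cycle *t*'s
person-years are the mean of state occupancy at boundaries *t−1* and
*t*. The default discounting convention indexes the whole of cycle *t*'s
flow at the end of the cycle, factor (1+r)⁻ᵗ with r = 0.03; a mid-cycle
convention ((1+r)^−(t−½)) is selectable in the configuration
(`discounting: mid_cycle`). Under the default the 10-year discounted
program-cost stream is 36 × Σₜ 1.03⁻ᵗ = 36 × 8.5302 ≈ SGD 307.1M;
mid-cycle would give ≈311.7M.

Uncomplicated disease states cost `inpatient_proportion ×
cost_inpatient + (1 − inpatient_proportion) × cost_outpatient` per
person-year (times the PA cost multiplier in the scenario analysis);
complication states cost their full inpatient rate; healthy states are
costless. The societal perspective adds indirect costs as direct/ratio
per disease (direct-to-indirect ratio ≈ 0.45–0.5, i.e. roughly SGD 2 of
productivity loss per SGD 1 of treatment). The annual program cost
accrues only in the intervention situation, undiminished by deaths
(program spend is population-level), and is reported separately from
health-care costs. Cases and deaths averted are differences of
cumulative incident flows (control − intervention), not prevalence
differences. Deaths accrue nothing beyond the half-cycle convention in
their final cycle.

## Uncertainty analyses

- **PSA.** Every non-degenerate, non-excluded parameter is drawn
  independently from its distribution; the full model (both situations)
  runs per draw; point estimates are sample means and 95% credible
  intervals the 2.5/97.5 percentiles (linear interpolation between
  order statistics — numpy/pandas default, fixed and documented). Each
  parameter owns an independent random stream derived from the master
  seed and the parameter's name (CRC-32), so the draw for one parameter
  never depends on which others exist — stable for regression tests.
  The time horizon is never sampled (`psa_exclude`), matching the
  convention that the horizon is a policy choice: 32 parameters vary in
  the PSA, 33 in the one-way analysis.
- **Cost-effectiveness probability.** Computed as the fraction of
  samples with positive net monetary benefit, λ·ΔQALY − ΔCost > 0. When
  every sample gains QALYs this equals the share of ICERs below λ; the
  net-benefit form stays well-defined if a sample loses QALYs.
- **One-way DSA.** Bounds per range rule: `ci95` = the distribution's
  2.5/97.5 quantiles; `iqr` = 25/75 quantiles (unit costs); `pm30` =
  0.7/1.3 × base (program cost, compliance, inpatient proportions, time
  horizon). Bounds falling outside a parameter's domain are clamped to
  the domain with a logged warning. The horizon's ±30% bounds round to
  whole cycles (7 and 13 years). Entries sort by descending bar width
  |ICER(hi) − ICER(lo)| and are invariant to evaluation order.
- **Threshold analysis.** Bisection on the deterministic ICER until the
  bracket is narrower than `tol` (default 10⁻⁶ of the initial width);
  where the ICER is undefined (ΔQALY = 0, e.g. compliance = 0) the sign
  of the net cost stands in. Same-signed bracket ends return a
  no-threshold signal, not an error.
- **Scenario.** `apply_cost_differentiation(δ)` multiplies
  inactive-level disease-state costs by 1+δ and moderate-to-high by
  1−δ (default δ = 0.05); complication states are untouched.

## Synthetic parameter generator

The generator stands in for the study's supplementary parameter table,
which is not redistributable. Anchored exactly: program cost SGD 36M/yr,
compliance 0.385, discount 3%, horizon 10 years, WTP grid {0, 5000,
10000} SGD/QALY, 1.7M registrants. Everything else is drawn from
documented plausible ranges with a small seeded jitter: logistic age
curves for prevalence and incidence (diabetes incidence plateau
2.5%/yr, hypertension 6%/yr, complications 5.5%/4.0%/yr among the
diseased), Gompertz-like mortality capped at 0.18/yr, protective RRs for
higher activity (incidence ≈0.58–0.84, mortality ≈0.78–0.90,
complication-state mortality multipliers ≈3.0/2.6), utilities ordered
healthy ≥ disease ≥ complication with u(healthy, moderate-to-high)
fixed at 1.0 as the perfect-health anchor, and inpatient costs SGD
12k/8k for uncomplicated disease vs 28k/25k for complications. These
magnitudes place the default full-scale run in the marginally
cost-saving regime — case aversion outweighing the survival-cost
offset — which is the qualitative regime the analysis is designed to
probe; the resulting compliance break-even sits just below the base
38.5%.

Exactly 33 parameters carry non-degenerate distributions at full scale:
4 incidence RRs, 6 living-group mortality RRs, 2 complication mortality
multipliers, 10 utilities, 4 inpatient and 2 outpatient costs, 2
inpatient proportions, program cost, compliance and the horizon.
Conventional families are used — beta for probabilities and utilities,
gamma for costs, lognormal for relative risks (medians at the base
value) — overridable per parameter in the configuration. Direct-to-
indirect ratios are held at point estimates.

What the generator does **not** emulate: real census age structure,
correlation between parameters (draws are independent), secular trends
in incidence or mortality, cost inflation, or any attempt to infer the
actual supplementary-table values. Passing tests therefore demonstrate
the correctness and internal consistency of the machinery under
realistic conditions, not agreement of headline projections with the
published cohort — except for the quantities that depend only on
main-text inputs (cohort size, completion fraction, discounted program
cost), which are reproduced exactly or within Monte-Carlo error.

## Verification strategy and problem sizes

- The microsimulation oracle shares only the factor-matrix construction
  with the cohort engine and re-derives occupancy and outcomes by
  simulating individuals; agreement within 3 standard errors at 10,000
  individuals is asserted in the suite.
- Closed-form checks: the immortal healthy unit cohort reproduces the
  discounted annuity Σₜ 1.03⁻ᵗ = 8.5302; an all-degenerate PSA equals
  the deterministic run exactly; bisection roots are re-verified by
  direct model evaluation and by an independent grid scan.
- Row-stochasticity (≤10⁻¹²) is swept over 1000 generated parameter
  sets; cohort conservation (≤10⁻⁶ persons at N = 654,500) over the
  full horizon.
- Routine test sizes: toy scale (3 age bands) for exact and oracle
  tests, full scale (15 bands) for pipeline and ordering checks; the
  PSA mean of the program cost uses the full 1000 samples.

## Known limitations

- No comorbid diabetes+hypertension state and no remission/recovery.
- Disease states carry no excess mortality relative to healthy at equal
  activity (all excess risk routed through complications).
- PA levels in the no-program situation are static by default
  (`control_pa_shift` = identity); secular drift can be configured but
  is not generated.
- Parameter draws in the PSA are independent; orderings guaranteed at
  the base case (e.g. complication utility ≤ parent disease utility)
  can be violated in the tails of a joint draw, which is accepted
  rather than re-sampled.
- The fractional band-aging flow slightly smears age cohorts relative
  to exact per-age bookkeeping; the microsim oracle uses the matched
  stochastic version, so the comparison is internally consistent.
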