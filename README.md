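# stepcea

Cost-utility analysis of a nationwide incentive-based physical-activity
program, built as a closed-cohort Markov state-transition model with full
uncertainty analysis.

## The problem

Population-scale step challenges (the modeled case: ~654,500 adult
participants, SGD 36 million per year of program cost) aim to delay
diabetes and hypertension by raising physical activity. Whether such a
program pays for itself is a health-economics question: over a 10-year
horizon, do the averted cases, complications and deaths gain enough
quality-adjusted life-years (QALYs) and save enough treatment cost to
justify the spend? `stepcea` answers it with the standard machinery of
model-based economic evaluation, for analysts who want a tested,
configuration-driven, reproducible pipeline rather than a spreadsheet.

## The model

A closed cohort aged 17+ moves annually through **12 states**: {healthy,
diabetes, hypertension} × {inactive, low, moderate-to-high physical
activity} (9 living states), cardiovascular disease (the diabetes
complication), stroke (the hypertension complication), and death.
Complication states are chronic, all-inpatient, and carry no PA level;
death is absorbing; nobody holds both diseases.

Each one-year cycle composes three row-stochastic factors, in order:
PA-level shift (the program moves a compliant fraction *c* = 0.385
upward), disease/complication onset, and death. Population incidence
*i* is calibrated to an inactive-reference rate *i₀* by prevalence
weighting, Σₖ πₖ·RRₖ·i₀ = i, and per-level rates RRₖ·i₀ convert to
probabilities as 1 − exp(−rate). Costs and QALYs accrue with half-cycle
correction and discounting at *r* = 3%/yr:

- QALYs = Σₜ (1+r)⁻ᵗ · ½(nₜ₋₁ + nₜ)ᵀu, with utilities u ∈ [0,1];
- ICER = (program cost − health-care cost reduction) / QALYs gained;
  the program is **cost-saving** (ICER < 0) when it gains QALYs and
  saves more than it costs;
- probabilistic SA: 1000 joint draws of the 32 uncertain parameters,
  means and 2.5/97.5-percentile credible intervals, CEAC via net
  monetary benefit λ·ΔQ − ΔC > 0;
- one-way SA over 33 parameters (95% CI / IQR / ±30% ranges), threshold
  (break-even) bisection, and a ±5% PA-cost-differentiation scenario.

The published supplementary parameter table is not redistributable, so a
first-class synthetic generator (`generate_parameter_set`) produces
schema-valid stand-in parameter sets anchored to the main-text economics
and with the qualitative epidemiology the analysis assumes. An
individual-level microsimulation oracle cross-validates the cohort
engine.

## Worked example

```python
from stepcea import evaluate, generate_parameter_set
from stepcea.io import headline

params = generate_parameter_set(seed=1, scale="full")
print(headline(evaluate(params)))
```

prints (3-significant-figure presentation):

```
Cohort size: 655,000 participants
Diabetes cases averted: 3,470
Hypertension cases averted: 5,380
Deaths averted: 3,900
QALYs gained: 71,500
Health-care cost reduction: SGD 332,000,000
Societal cost reduction: SGD 1,010,000,000
Program cost (discounted, 10y): SGD 307,000,000
ICER (health system): SGD -344 per QALY
Classification: cost-saving
```

Read it as: under these synthetic conditions the program averts ~8,850
disease cases and ~3,900 deaths over 10 years, gains ~71,500 discounted
QALYs, and saves SGD 332M in treatment costs against a SGD 307M
discounted program cost — a negative ICER, i.e. cost-saving from the
health-system perspective, and more so societally. The `examples/`
scripts walk through the PSA/CEAC, tornado, threshold, scenario and
microsimulation checks one capability at a time; a thin CLI (`stepcea
synth|run|psa|dsa|threshold|scenario|validate|schema`) wraps the same
functions for shell use.

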