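"""Probabilistic sensitivity analysis and the acceptability curve.

Draws 200 joint samples of the 32 uncertain parameters (the time horizon
is never sampled), re-runs the model per draw, and prints the PSA mean
with its 2.5/97.5-percentile credible interval plus the probability the
program is cost-effective at each willingness-to-pay threshold.
"""

from stepcea import generate_parameter_set, run_psa

params = generate_parameter_set(seed=1, scale="full")
psa = run_psa(params, n_samples=200, seed=1)

rows = ["qalys_gained", "healthcare_cost_reduction", "societal_cost_reduction", "program_cost"]
print(psa.summary.loc[rows].to_string(float_format=lambda v: f"{v:,.0f}"))
print()
for persp, probs in psa.ce_probability.items():
    pretty = ", ".join(f"WTP {int(w):,}: {p:.1%}" for w, p in probs.items())
    print(f"P(cost-effective | {persp}): {pretty}")
print(
    "\nThe credible intervals come from the 2.5/97.5 percentiles of the samples;\n"
    "the probabilities are the share of samples with positive net monetary benefit."
)
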