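"""Break-even (threshold) analysis: where does the decision flip?

Bisects a parameter until the deterministic ICER crosses zero. With the
default synthetic conditions the program is marginally cost-saving, so a
compliance threshold exists just below the base 38.5%.
"""

from stepcea import generate_parameter_set, threshold_search

params = generate_parameter_set(seed=1, scale="full")

for name, bracket in [("compliance", (0.0, 1.0)), ("program_cost_annual", (0.0, 80e6))]:
    res = threshold_search(params, name, bracket)
    if res is None:
        print(f"{name}: no break-even point inside {bracket}")
    else:
        word = "at least" if res.direction == "at_least" else "at most"
        print(
            f"{name}: cost-saving requires {word} {res.threshold:,.4g} "
            f"(ICER at the root: {res.icer_at_threshold:+.2f} SGD/QALY)"
        )
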