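"""Base case: expected six-month costs and QALYs for the four arms.

Builds each arm's decision tree from the packaged base-case parameters
and prints expected healthcare/societal costs and QALYs at the lowest
and highest psilocybin prices.  Higher QALYs are better; a costlier arm
can still be worthwhile if it buys enough QALYs (see icer_curves.py).
"""

from psilocea import arm_results, paper_fixture

params = paper_fixture()
for price in (400, 2000):
    print(f"\npsilocybin price GBP {price}:")
    print(f"{'arm':8} {'healthcare':>12} {'societal':>10} {'QALYs':>7}")
    for arm_id, res in arm_results(params, price).items():
        print(
            f"{arm_id:8} {res.expected_cost_healthcare:12.0f} "
            f"{res.expected_cost_societal:10.0f} {res.expected_qalys:7.3f}"
        )
print(
    "\nPAP accrues the most QALYs (0.310 vs 0.276-0.287) but costs the most; "
    "its healthcare cost rises with the drug price at slope "
    f"{params.costs.drug_cost_weight}."
)
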