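"""ICER-versus-price curves for PAP against each comparator.

Prints the incremental cost-effectiveness ratio (GBP per QALY gained by
choosing PAP) at each psilocybin price, under both perspectives.  Values
below the GBP 20 000-30 000 NICE range indicate cost-effectiveness.
"""

from psilocea import Perspective, icer_grid, paper_fixture

params = paper_fixture()
grid = icer_grid(params)
for perspective in ("healthcare", "societal"):
    print(f"\n{perspective} perspective (ICER, GBP/QALY):")
    sub = grid[grid.perspective == perspective]
    table = sub.pivot(index="price", columns="comparison", values="icer")
    print(table.round(0).to_string())
print(
    "\nHealthcare-perspective ICERs all exceed 30 000, so PAP at trial-level "
    "therapist support is not cost-effective there; societal ICERs at low "
    "prices fall below 30 000 against the SSRI and CBT comparators."
)
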