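"""Ranking counties by credit cost vs additional-sequestration cost.

The two objectives disagree: producing cheap credits favours
fast-adopting counties (many enrollees to spread the fixed cost over),
while buying *additional* tons cheaply favours slow-adopting counties
(fewer non-additional enrollees on the payroll).
"""

from agtarget import RoundingPolicy, rank_counties
from agtarget.worked_example import worked_example_program, worked_example_scenarios

scenarios = worked_example_scenarios()
program = worked_example_program()
pct = RoundingPolicy("nearest_percent")
four = [scenarios[k] for k in ("A^low", "A^high", "B^low", "B^high")]

for metric in ("per_credit", "per_additional_ton"):
    ranked = rank_counties(four, program, metric, pct)
    print(f"ranked by {metric} (best first):")
    for sc, _, met in ranked:
        value = met.ac_per_credit if metric == "per_credit" else met.ac_per_additional_ton
        print(f"  {sc.model.county_id}(seq={sc.seq_rate:.0f}t): ${value:.2f}")
    print()

print(
    "Note the reversal: A^low beats B^low on credit cost ($0.41 < $0.45)\n"
    "but loses badly per additional ton ($1.86 > $1.25).  A mixed case:\n"
    "B^mid (1.5 t/adopter) undercuts even the high-sequestration fast\n"
    "county A^high per additional ton ($0.83 < $0.93), so targeting by\n"
    "sequestration rate alone is not optimal."
)
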