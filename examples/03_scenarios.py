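"""Direct lifetime costs for the 18 start-characteristic scenarios.

Scenario labels combine start age (50/75), residence (C community /
N nursing home), disease status (O osteoporosis / avO average risk /
nO never) and fracture history (P prevalent fracture / nP none).
"""

import osteosim as om
from osteosim.experiments import run_scenarios

params = om.default_parameter_set()
df = run_scenarios(params, n=10_000, seed=1)

print(df[["direct_cost_undiscounted", "direct_cost_discounted"]].round(0))

o = df.loc["50_C_O_nP", "direct_cost_discounted"]
no = df.loc["50_C_nO_nP", "direct_cost_discounted"]
print(f"\nA 50 year old with osteoporosis costs {o / no:.1f}x a woman never "
      f"at risk ({o:.0f} vs {no:.0f} EUR discounted).")
# Nursing-home scenarios cost less despite higher fracture risk: mortality
# is higher and no home care, informal care or attributable long-term-care
# costs apply to institutionalized women.
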