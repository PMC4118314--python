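"""Lifetime fracture costs by healthcare sector, and the osteoporosis excess.

The excess (attributable) cost is the difference between the average-risk
and the never-osteoporosis cohort, simulated on common random numbers so
the difference is free of first-order Monte Carlo noise.
"""

import osteosim as om

params = om.default_parameter_set()
result = om.run_base_case(params, n=20_000, seed=1)

print("Discounted (3%) lifetime direct costs per capita, EUR 2009\n")
print(f"{'sector':<24}{'average risk':>14}{'never osteo':>14}{'excess':>12}")
for sector in om.SECTORS[:6]:
    a = result.average.sector_costs.loc[sector, "discounted"]
    n = result.never.sector_costs.loc[sector, "discounted"]
    print(f"{sector:<24}{a:>14.0f}{n:>14.0f}{a - n:>12.0f}")
ta = result.average.total_direct["discounted"]
tn = result.never.total_direct["discounted"]
print(f"{'total direct':<24}{ta:>14.0f}{tn:>14.0f}{ta - tn:>12.0f}")

hca = result.excess.sector_costs.loc["productivity_hca", "discounted"]
fca = result.excess.sector_costs.loc["productivity_fca", "discounted"]
print(f"\nExcess productivity costs: {hca:.0f} EUR (human capital), "
      f"{fca:.0f} EUR (friction cost)")
# The total-direct excess is the per-woman lifetime cost that would be
# avoided in a population never developing osteoporosis.
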