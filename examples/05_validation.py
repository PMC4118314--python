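"""Internal validation: modeled vs expected fracture incidence.

Simulates the average-risk population and compares the modeled age-class
incidence of hip fractures with the general-population input probabilities;
with correctly calibrated subgroup relative risks the two agree up to
Monte Carlo error and mortality-selection effects at the highest ages.
"""

import osteosim as om
from osteosim.experiments import internal_validation

params = om.default_parameter_set()
v = internal_validation(params, n=50_000, seed=1)

hip = v.rates[v.rates.fracture_type == "hip"]
print(hip[["age_class", "expected", "modeled", "person_years"]]
      .to_string(index=False, float_format=lambda x: f"{x:.4f}"))

print("\nProportion of women with 0,1,2,... hip fractures:")
print(v.count_distribution.loc["hip"].map("{:.2%}".format).to_string())
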