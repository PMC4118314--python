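"""Default parameter tables, random-but-valid parameter generators, toy worlds.

The defaults combine the printed inputs of the German fracture model — the
age-specific total fracture probabilities of the female general population
and the 2009 unit costs per fracture type and sector — with clearly flagged
placeholder values for everything published only in supplementary material
(mortality relative risks, nursing-home admission probabilities, BMD
gradients and T-score ladders, previous-fracture meta-analysis inputs,
resource use and employment figures).  Placeholders carry
``provenance="placeholder"`` and sit at plausible published magnitudes; the
CSV files written by :func:`default_parameter_tables` are the drop-in
editing surface for replacing them with transcribed values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .parameters import (
    AGE_MAX,
    AGE_MIN,
    FractureType,
    N_AGE_CLASSES,
    N_MORTALITY_AGE_CLASSES,
    N_TYPES,
    ParameterInputs,
    ParameterSet,
    build_parameter_set,
    write_parameter_tables,
)

# ---------------------------------------------------------------------------
# Printed inputs
# ---------------------------------------------------------------------------

#: Total yearly fracture probability of the female general population,
#: by 5-year age class (50-54 … 95+), per fracture type.
TABLE1_FRACTURE_PROBABILITIES: dict[str, tuple[float, ...]] = {
    "hip": (0.00038, 0.00071, 0.00104, 0.00187, 0.00334,
            0.00772, 0.01605, 0.02791, 0.03625, 0.03960),
    "other_femur": (0.00010, 0.00014, 0.00021, 0.00033, 0.00054,
                    0.00102, 0.00162, 0.00262, 0.00324, 0.00382),
    "clinical_vertebral": (0.00095, 0.00144, 0.00192, 0.00316, 0.00456,
                           0.00634, 0.01132, 0.01378, 0.01339, 0.01052),
    "humerus": (0.00085, 0.00143, 0.00194, 0.00272, 0.00360,
                0.00530, 0.00716, 0.00872, 0.00861, 0.00795),
    "pelvis": (0.00018, 0.00028, 0.00038, 0.00071, 0.00127,
               0.00285, 0.00544, 0.00890, 0.01172, 0.01118),
    "wrist": (0.00221, 0.00390, 0.00491, 0.00620, 0.00684,
              0.00866, 0.00973, 0.00916, 0.00740, 0.00530),
}

#: Direct unit costs in EUR (2009 price level) by cost category and type.
#: Hospital figures include post-hospital outpatient aftercare; outpatient
#: figures apply only when no hospitalization occurs (not applicable for the
#: always-hospitalized femoral fractures, stored as 0 and never drawn).
TABLE2_UNIT_COSTS: dict[str, tuple[float, ...]] = {
    "hospital": (8554, 8395, 6324, 5764, 5005, 3794),
    "rehabilitation": (2187, 2187, 2092, 2337, 2177, 2337),
    "outpatient": (0, 0, 1614, 835, 963, 835),
    "home_care": (2174, 2174, 2212, 937, 2174, 525),
    "informal_care": (2361, 2361, 2016, 2961, 2361, 581),
}

LTC_YEARLY_COST = 25_759.0


def _life_table_q() -> np.ndarray:
    """Placeholder 1959 birth-cohort female life table (Gompertz, ages 50-100)."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    return np.minimum(1.05e-5 * np.exp(0.105 * ages), 0.40)


def _fracture_mortality_rr() -> np.ndarray:
    """Placeholder excess-mortality RRs per type x 10-year age class x bucket.

    Buckets: fracture year, years 2-5, years 6-10; wrist fractures carry no
    excess mortality.  The relative excess declines with age.
    """
    base = {
        "hip": (3.5, 2.0, 1.5),
        "other_femur": (3.5, 2.0, 1.5),
        "clinical_vertebral": (2.7, 1.8, 1.4),
        "humerus": (1.9, 1.4, 1.2),
        "pelvis": (2.2, 1.6, 1.3),
        "wrist": (1.0, 1.0, 1.0),
    }
    age_factor = np.array([1.4, 1.2, 1.0, 0.85, 0.7])
    out = np.ones((N_TYPES, N_MORTALITY_AGE_CLASSES, 3))
    for f in FractureType:
        b = np.asarray(base[f.label])
        # scale the excess (RR - 1), never dropping below no excess
        out[f] = np.maximum(1.0 + (b[np.newaxis, :] - 1.0) * age_factor[:, np.newaxis], 1.0)
    return out


def default_inputs() -> ParameterInputs:
    """The shipped default :class:`ParameterInputs` with provenance tags."""
    p_general = np.array([TABLE1_FRACTURE_PROBABILITIES[f.label] for f in FractureType])

    hip_gradient = np.array([3.68, 3.5, 3.3, 3.1, 2.9, 2.7, 2.5, 2.3, 2.1, 1.9])
    flat = {"other_femur": (2.3, 1.9, 2.8), "clinical_vertebral": (1.8, 1.1, 2.7),
            "humerus": (1.9, 1.4, 2.5), "pelvis": (1.6, 1.2, 2.1), "wrist": (1.4, 1.2, 1.7)}
    gradient = np.ones((N_TYPES, N_AGE_CLASSES))
    glo = np.ones_like(gradient)
    ghi = np.ones_like(gradient)
    gradient[FractureType.HIP] = hip_gradient
    glo[FractureType.HIP] = np.maximum(hip_gradient * 0.85, 1.0)
    ghi[FractureType.HIP] = hip_gradient * 1.15
    for name, (mid, lo, hi) in flat.items():
        f = FractureType[name.upper()]
        gradient[f], glo[f], ghi[f] = mid, lo, hi

    hip_admission = np.array([0, 0, 0, 0.05, 0.08, 0.12, 0.18, 0.24, 0.28, 0.30])
    admission_scale = {"hip": 1.0, "other_femur": 1.0, "clinical_vertebral": 0.4,
                       "humerus": 0.3, "pelvis": 0.5, "wrist": 0.15}
    admission = np.array([hip_admission * admission_scale[f.label] for f in FractureType])

    provenance = {
        "general_fracture_probability": "table1",
        "hospital_cost": "table2",
        "rehabilitation_cost": "table2",
        "outpatient_cost": "table2",
        "home_care_cost": "table2",
        "informal_care_cost": "table2",
        "ltc_yearly_cost": "table2",
        "discount_rate": "paper_text",
        "base_year": "paper_text",
        "wage_growth": "paper_text",
        "min_nh_entry_age": "paper_text",
        "bmd_threshold": "paper_text",
    }
    for name in ("hospitalization_probability", "rehabilitation_probability",
                 "rr_any_previous", "rr_hip_previous", "rr_osteo_previous",
                 "previous_fracture_prevalence", "gradient_of_risk", "mean_tscore",
                 "osteo_prevalence_scale", "care_prevalence", "nh_admission_probability",
                 "rr_fracture_nh", "all_cause_mortality", "rr_fracture_mortality",
                 "rr_mortality_nh", "employment_rate", "yearly_earnings",
                 "work_days_lost", "friction_period_years", "working_days_per_year",
                 "retirement_age", "informal_valuation_factor", "trend_rate"):
        provenance[name] = "placeholder"
    # femoral hospitalization shares are stated in the text (100% inpatient)
    provenance["hospitalization_probability"] = "placeholder"  # non-femoral shares

    return ParameterInputs(
        p_general=p_general,
        hospitalization_prob=np.array([1.0, 1.0, 0.39, 0.56, 0.79, 0.27]),
        rehab_prob=np.array([0.5, 0.5, 0.3, 0.3, 0.4, 0.1]),
        rr_any_prev=1.86, rr_any_prev_ci=(1.75, 1.98),
        rr_hip_prev=1.85, rr_hip_prev_ci=(1.58, 2.17),
        rr_osteo_prev=1.86, rr_osteo_prev_ci=(1.75, 1.98),
        prev_previous_fx=np.array([0.15, 0.18, 0.22, 0.26, 0.30,
                                   0.34, 0.38, 0.41, 0.44, 0.45]),
        gradient_of_risk=gradient, gradient_low=glo, gradient_high=ghi,
        mean_tscore=np.array([-1.0, -1.2, -1.4, -1.6, -1.8,
                              -1.95, -2.1, -2.2, -2.3, -2.4]),
        bmd_threshold=-2.5,
        care_prevalence=np.array([0, 0, 0, 0.01, 0.02, 0.045, 0.09, 0.17, 0.27, 0.36]),
        nh_admission_prob=admission,
        rr_fracture_nh=np.array([2.2, 2.2, 1.5, 1.5, 1.8, 0.8]),
        min_nh_entry_age=65,
        all_cause_q=_life_table_q(),
        rr_fracture_mortality=_fracture_mortality_rr(),
        rr_mortality_nh=2.0,
        hospital_cost=np.asarray(TABLE2_UNIT_COSTS["hospital"], dtype=float),
        rehab_cost=np.asarray(TABLE2_UNIT_COSTS["rehabilitation"], dtype=float),
        outpatient_cost=np.asarray(TABLE2_UNIT_COSTS["outpatient"], dtype=float),
        home_care_cost=np.asarray(TABLE2_UNIT_COSTS["home_care"], dtype=float),
        informal_care_cost=np.asarray(TABLE2_UNIT_COSTS["informal_care"], dtype=float),
        ltc_yearly_cost=LTC_YEARLY_COST,
        discount_rate=0.03,
        base_year=2009,
        employment_rate=np.array([0.77, 0.70, 0.38, 0, 0, 0, 0, 0, 0, 0]),
        yearly_earnings=43_200.0,
        work_days_lost=np.array([110.0, 110.0, 90.0, 60.0, 80.0, 35.0]),
        friction_period_years=0.25,
        working_days_per_year=250.0,
        wage_growth=0.02,
        retirement_age=65,
        provenance=provenance,
    )


def default_parameter_set() -> ParameterSet:
    return build_parameter_set(default_inputs())


def default_parameter_tables(out_dir) -> list[Path]:
    """Write the shipped defaults as editable CSV tables; returns the paths."""
    return write_parameter_tables(default_inputs(), out_dir)


# ---------------------------------------------------------------------------
# Random-but-valid parameter sets for property testing
# ---------------------------------------------------------------------------


def random_valid_parameters(seed: int, scale: float = 0.4) -> ParameterInputs:
    """Sample a parameter set satisfying every type invariant by construction.

    Perturbations are bounded multiplicative/additive noise around the
    defaults, applied so that monotone prevalence ladders stay monotone and
    consistency-calibrated quantities remain derivable (the calibration
    operations themselves enforce the prevalence-weighted RR identities).
    ``scale`` in [0, 1] controls the perturbation width; 0 returns the
    defaults unchanged.
    """
    if not 0.0 <= scale <= 1.0:
        raise ValueError("scale must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    inp = default_inputs()

    def mult(lo, hi, size=None):
        return rng.uniform(1 - (1 - lo) * scale, 1 + (hi - 1) * scale, size=size)

    inp.p_general = np.clip(inp.p_general * mult(0.5, 1.5, inp.p_general.shape), 0, 0.9)
    inp.hospitalization_prob = np.where(
        inp.hospitalization_prob == 1.0, 1.0,
        np.clip(inp.hospitalization_prob * mult(0.6, 1.4, N_TYPES), 0.05, 1.0))
    inp.rehab_prob = np.clip(inp.rehab_prob * mult(0.5, 1.5, N_TYPES), 0, 1)
    inp.rr_any_prev = float(inp.rr_any_prev * mult(0.7, 1.3))
    inp.rr_hip_prev = float(inp.rr_hip_prev * mult(0.7, 1.3))
    inp.rr_osteo_prev = float(inp.rr_osteo_prev * mult(0.7, 1.3))
    # common multiplier keeps the ladder monotone
    inp.prev_previous_fx = np.clip(inp.prev_previous_fx * mult(0.6, 1.3), 0, 0.95)
    inp.gradient_of_risk = 1.0 + (inp.gradient_of_risk - 1.0) * mult(0.5, 1.3)
    inp.mean_tscore = inp.mean_tscore + rng.uniform(-0.3, 0.3) * scale
    inp.care_prevalence = np.clip(inp.care_prevalence * mult(0.5, 1.2), 0, 0.5)
    inp.nh_admission_prob = np.clip(inp.nh_admission_prob * mult(0.5, 1.5), 0, 1)
    inp.rr_fracture_nh = inp.rr_fracture_nh * mult(0.8, 1.2, N_TYPES)
    inp.all_cause_q = np.clip(inp.all_cause_q * mult(0.7, 1.3), 0, 1)
    inp.rr_fracture_mortality = 1.0 + (inp.rr_fracture_mortality - 1.0) * mult(0.5, 1.5)
    inp.rr_mortality_nh = float(np.clip(inp.rr_mortality_nh * mult(0.8, 1.2), 1.0, 2.5))
    for attr in ("hospital_cost", "rehab_cost", "outpatient_cost",
                 "home_care_cost", "informal_care_cost", "work_days_lost"):
        setattr(inp, attr, getattr(inp, attr) * mult(0.5, 2.0, N_TYPES))
    inp.ltc_yearly_cost = float(inp.ltc_yearly_cost * mult(0.5, 2.0))
    inp.yearly_earnings = float(inp.yearly_earnings * mult(0.6, 1.5))
    inp.employment_rate = np.clip(inp.employment_rate * mult(0.6, 1.2), 0, 1)
    return inp


# ---------------------------------------------------------------------------
# Toy worlds with closed-form expectations
# ---------------------------------------------------------------------------


def homogeneous_inputs(no_mortality: bool = True) -> ParameterInputs:
    """Defaults with every relative risk forced to 1 (optionally mortality off).

    In this degenerate world every risk group has identical fracture
    probabilities, and with mortality off the expected lifetime count of
    type f is the plain sum of its annual probabilities over ages 50-99.
    """
    inp = default_inputs()
    inp.gradient_of_risk = np.ones((N_TYPES, N_AGE_CLASSES))
    inp.gradient_low = np.ones((N_TYPES, N_AGE_CLASSES))
    inp.gradient_high = np.ones((N_TYPES, N_AGE_CLASSES))
    inp.rr_any_prev = inp.rr_hip_prev = inp.rr_osteo_prev = 1.0
    inp.rr_fracture_nh = np.ones(N_TYPES)
    inp.rr_fracture_mortality = np.ones_like(inp.rr_fracture_mortality)
    inp.rr_mortality_nh = 1.0
    if no_mortality:
        inp.all_cause_q = np.zeros_like(inp.all_cause_q)
    return inp


def toy_world(name: str) -> tuple[ParameterSet, dict]:
    """A degenerate parameter set plus the closed-form expectations it implies.

    Catalogue:

    ``no_mortality_flat_hazard``
        Hip probability 0.01 per year, everything else off: expected
        lifetime hip count 0.5 over the 50 fracture-bearing years.
    ``certain_death_year1``
        Death probability 1 everywhere: exactly one simulated interval,
        lifetime costs are first-interval costs only.
    ``homogeneous_no_mortality``
        All RRs 1, mortality off: expected counts are the column sums of
        the general-population probability table over ages 50-99.
    """
    if name == "no_mortality_flat_hazard":
        inp = homogeneous_inputs(no_mortality=True)
        inp.p_general = np.zeros((N_TYPES, N_AGE_CLASSES))
        inp.p_general[FractureType.HIP, :] = 0.01
        return build_parameter_set(inp), {
            "expected_counts": {f.label: (0.5 if f == FractureType.HIP else 0.0)
                                for f in FractureType},
            "years_at_risk": 50,
        }
    if name == "certain_death_year1":
        inp = homogeneous_inputs(no_mortality=False)
        inp.all_cause_q = np.ones_like(inp.all_cause_q)
        return build_parameter_set(inp), {"expected_history_length": 1}
    if name == "homogeneous_no_mortality":
        inp = homogeneous_inputs(no_mortality=True)
        expected = {f.label: float(np.sum(inp.p_general[f] * 5.0)) for f in FractureType}
        return build_parameter_set(inp), {"expected_counts": expected, "years_at_risk": 50}
    raise KeyError(f"unknown toy world: {name!r}")
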