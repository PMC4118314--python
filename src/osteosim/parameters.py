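"""Model inputs and the risk-calibration arithmetic of the fracture simulation.

This module owns every epidemiological and cost input of the microsimulation
and the derivation formulas that turn published epidemiology into
simulation-ready, risk-group-specific annual probabilities:

* hospital-case inflation to total fracture probabilities (division by the
  fracture-specific hospitalization probability),
* the Schousboe consistency split for women with / without a previous
  fracture,
* the Kanis BMD-gradient derivation of the osteoporotic relative risk under
  unit-SD normal T-scores, with its Bleibler counterpart for women without
  osteoporosis,
* the Podgor–Leske prevalence-to-incidence conversion for irreversible
  conditions (used for osteoporosis onset and background nursing-home entry),
* per-age-class residence calibration (nursing home vs community).

Raw inputs live in :class:`ParameterInputs`; :func:`build_parameter_set`
validates them and precomputes every derived quantity into an immutable
:class:`ParameterSet` consumed by the simulation engines.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Domain enumerations and age-class structure
# ---------------------------------------------------------------------------


class FractureType(enum.IntEnum):
    """The six modeled fracture sites, in stable order.

    The integer value doubles as the random-stream slot offset of the site,
    so the ordering must never change between runs.
    """

    HIP = 0
    OTHER_FEMUR = 1
    CLINICAL_VERTEBRAL = 2
    HUMERUS = 3
    PELVIS = 4
    WRIST = 5

    @property
    def label(self) -> str:
        return self.name.lower()


N_TYPES = len(FractureType)

AGE_MIN = 50
AGE_MAX = 100  # women exit the model alive at the end of the age-100 interval

#: 5-year age bands covering ages 50-100 contiguously.
AGE_CLASS_LABELS: tuple[str, ...] = (
    "50-54", "55-59", "60-64", "65-69", "70-74",
    "75-79", "80-84", "85-89", "90-94", "95+",
)
N_AGE_CLASSES = len(AGE_CLASS_LABELS)

#: 10-year bands used by the fracture-mortality relative risks.
MORTALITY_AGE_CLASS_LABELS: tuple[str, ...] = ("50-59", "60-69", "70-79", "80-89", "90+")
N_MORTALITY_AGE_CLASSES = len(MORTALITY_AGE_CLASS_LABELS)

#: years-since-fracture buckets of the excess-mortality relative risks
MORTALITY_BUCKET_LABELS: tuple[str, ...] = ("1", "2-5", "6-10")


def age_class_index(age):
    """Map integer age(s) in [50, 100] to the 5-year band index (piecewise constant)."""
    age = np.asarray(age)
    if np.any((age < AGE_MIN) | (age > AGE_MAX)):
        raise ValueError(f"age outside [{AGE_MIN}, {AGE_MAX}]")
    idx = np.minimum((age - AGE_MIN) // 5, N_AGE_CLASSES - 1)
    return idx if idx.ndim else int(idx)


def mortality_age_class_index(age):
    """Map integer age(s) to the 10-year excess-mortality band index."""
    age = np.asarray(age)
    idx = np.minimum((age - AGE_MIN) // 10, N_MORTALITY_AGE_CLASSES - 1)
    return idx if idx.ndim else int(idx)


@dataclass(frozen=True)
class AgeClassSchedule:
    """One real value per 5-year age band (50-54 … 95+), piecewise constant.

    Lookups never interpolate: any integer age in [50, 100] resolves to
    exactly one band, matching how the inputs are published.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_AGE_CLASSES:
            raise ValueError(f"expected {N_AGE_CLASSES} band values, got {len(self.values)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("age-class schedule contains non-finite values")

    def at_age(self, age: int) -> float:
        return self.values[age_class_index(age)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


class ParameterError(ValueError):
    """Raised when the input tables fail validation; carries all issues at once."""

    def __init__(self, issues: Iterable[str]):
        self.issues = list(issues)
        super().__init__("invalid parameters:\n  - " + "\n  - ".join(self.issues))


# ---------------------------------------------------------------------------
# Derivation formulas
# ---------------------------------------------------------------------------


def derive_total_fracture_probability(hospital_case_rate, hospitalization_prob):
    """Inflate a hospital-case rate to a total annual fracture probability.

    Hospital discharge statistics miss fractures treated exclusively in the
    outpatient sector; dividing by the (age-independent) hospitalization
    probability recovers the total probability.  Results above 1 are clipped
    with a warning.
    """
    rate = np.asarray(hospital_case_rate, dtype=float)
    hp = np.asarray(hospitalization_prob, dtype=float)
    if np.any(hp <= 0.0) or np.any(hp > 1.0):
        raise ParameterError(["hospitalization probability must lie in (0, 1]"])
    if np.any(rate < 0.0):
        raise ParameterError(["hospital case rate must be >= 0"])
    p = rate / hp
    n_clipped = int(np.count_nonzero(p > 1.0))
    if n_clipped:
        log.warning("derive_total_fracture_probability: clipped %d value(s) to 1", n_clipped)
        p = np.minimum(p, 1.0)
    return p if p.ndim else float(p)


def rr_no_previous_fracture(rr_any_prev, prev):
    """Relative risk of women *without* a previous fracture vs the general population.

    Schousboe-style consistency split: RR = 1 / (1 + (RR_any - 1) * prev),
    so that prev * RR_any * RR + (1 - prev) * RR == 1 exactly.
    """
    rr = np.asarray(rr_any_prev, dtype=float)
    p = np.asarray(prev, dtype=float)
    if np.any(rr <= 0):
        raise ParameterError(["rr_any_prev must be > 0"])
    if np.any((p < 0) | (p > 1)):
        raise ParameterError(["previous-fracture prevalence must lie in [0, 1]"])
    out = 1.0 / (1.0 + (rr - 1.0) * p)
    return out if out.ndim else float(out)


def fracture_prob_by_history(p_general, rr_no_prev, rr_prev_given_type, has_previous):
    """Annual fracture probability adjusted for previous-fracture status.

    Women without a previous fracture get ``p_general * rr_no_prev``; women
    with one additionally carry the type-specific subsequent-fracture RR
    (hip uses the hip-specific RR, the five other sites the osteoporotic-
    fracture RR).  Clipped to [0, 1] with a warning.
    """
    p = np.asarray(p_general, dtype=float) * np.asarray(rr_no_prev, dtype=float)
    p = np.where(has_previous, p * np.asarray(rr_prev_given_type, dtype=float), p)
    n_clipped = int(np.count_nonzero(p > 1.0))
    if n_clipped:
        log.warning("fracture_prob_by_history: clipped %d value(s) to 1", n_clipped)
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def rr_osteoporotic(gradient, mean_tscore, threshold=-2.5):
    """Relative fracture risk of the osteoporotic subgroup vs the whole population.

    Kanis-style derivation: femoral-neck T-scores are N(mean, 1); relative
    fracture risk scales as gradient**(-T) per SD of BMD.  The mean risk
    among women with T <= threshold relative to the population mean has the
    closed form  Phi(d + ln g) / Phi(d)  with d = threshold - mean.
    """
    g = np.asarray(gradient, dtype=float)
    if np.any(g < 1.0):
        raise ParameterError(["gradient of risk must be >= 1"])
    d = np.asarray(threshold, dtype=float) - np.asarray(mean_tscore, dtype=float)
    denom = norm.cdf(d)
    if np.any(denom < 1e-300):
        raise ParameterError(
            ["osteoporosis threshold lies too far below the population mean T-score "
             "(CDF underflow); use a coarser age class or an explicit RR override"]
        )
    out = norm.cdf(d + np.log(g)) / denom
    return out if out.ndim else float(out)


def rr_non_osteoporotic(rr_ost, prevalence):
    """Relative fracture risk of the non-osteoporotic subgroup vs the population.

    Bleibler-style consistency split: (1 - prev * RR_ost) / (1 - prev), so
    that prev * RR_ost + (1 - prev) * RR_noOst == 1 exactly.
    """
    rr = np.asarray(rr_ost, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    if np.any(p >= 1.0) or np.any(p < 0.0):
        raise ParameterError(["osteoporosis prevalence must lie in [0, 1)"])
    if np.any(rr * p >= 1.0):
        raise ParameterError(
            ["inconsistent inputs: prevalence * RR_ost >= 1 leaves the "
             "non-osteoporotic subgroup with non-positive risk"]
        )
    out = (1.0 - p * rr) / (1.0 - p)
    return out if out.ndim else float(out)


def prevalence_to_incidence(p_low, p_high, span_years, floor_at_zero=False):
    """Annual transition probability reproducing a prevalence ladder (Podgor–Leske).

    For an irreversible condition, the annual incidence q between two
    cross-sectional prevalences (span years apart, differential mortality
    ignored) is  q = 1 - ((1 - p_high) / (1 - p_low)) ** (1 / span).
    """
    lo = np.asarray(p_low, dtype=float)
    hi = np.asarray(p_high, dtype=float)
    if np.any((lo < 0) | (hi < 0) | (hi >= 1.0)):
        raise ParameterError(["prevalences must lie in [0, 1)"])
    if span_years <= 0:
        raise ParameterError(["span_years must be > 0"])
    if np.any(hi < lo):
        if not floor_at_zero:
            raise ParameterError(
                ["prevalence decreases over age; the condition is modeled as "
                 "irreversible (pass floor_at_zero=True to floor q at 0)"]
            )
        hi = np.maximum(hi, lo)
    q = 1.0 - ((1.0 - hi) / (1.0 - lo)) ** (1.0 / span_years)
    return q if q.ndim else float(q)


# ---------------------------------------------------------------------------
# Raw inputs
# ---------------------------------------------------------------------------

@dataclass
class ParameterInputs:
    """Raw, editable model inputs (before any derivation).

    Array axes: fracture type (6, :class:`FractureType` order), 5-year age
    class (10), mortality age class (5), years-since-fracture bucket (3).
    Every transformation used by the sensitivity analyses operates on this
    object and then rebuilds the derived :class:`ParameterSet`.
    """

    # fracture probabilities (general female population, per person-year)
    p_general: np.ndarray = None                 # (6, 10)
    hospitalization_prob: np.ndarray = None      # (6,)
    rehab_prob: np.ndarray = None                # (6,)

    # previous-fracture risk factor (with 95% CI bounds for S7/S8)
    rr_any_prev: float = 0.0
    rr_any_prev_ci: tuple[float, float] = (0.0, 0.0)
    rr_hip_prev: float = 0.0
    rr_hip_prev_ci: tuple[float, float] = (0.0, 0.0)
    rr_osteo_prev: float = 0.0
    rr_osteo_prev_ci: tuple[float, float] = (0.0, 0.0)
    prev_previous_fx: np.ndarray = None          # (10,)

    # osteoporosis risk factor
    gradient_of_risk: np.ndarray = None          # (6, 10); non-hip rows constant
    gradient_low: np.ndarray = None              # (6, 10) lower 95% bound (S9)
    gradient_high: np.ndarray = None             # (6, 10) upper 95% bound (S10)
    mean_tscore: np.ndarray = None               # (10,) population mean femoral-neck T-score
    bmd_threshold: float = -2.5
    osteo_prevalence_scale: float = 1.0          # S11/S12 multiplier

    # nursing home
    care_prevalence: np.ndarray = None           # (10,) NH population share by age
    nh_admission_prob: np.ndarray = None         # (6, 10) entry within 3 months of a hospitalized fracture
    rr_fracture_nh: np.ndarray = None            # (6,) fracture RR of NH residents vs general population
    min_nh_entry_age: int = 65

    # mortality
    all_cause_q: np.ndarray = None               # (51,) ages 50..100, 1959 birth-cohort life table
    rr_fracture_mortality: np.ndarray = None     # (6, 5, 3); wrist rows == 1
    rr_mortality_nh: float = 0.0

    # unit costs, EUR at 2009 price level
    hospital_cost: np.ndarray = None             # (6,) incl. post-hospital outpatient aftercare
    rehab_cost: np.ndarray = None                # (6,)
    outpatient_cost: np.ndarray = None           # (6,) exclusively-outpatient treatment (0 where n.a.)
    home_care_cost: np.ndarray = None            # (6,) professional home care, age > 65, community
    informal_care_cost: np.ndarray = None        # (6,) proxy-good valuation, age > 65, community
    ltc_yearly_cost: float = 0.0
    informal_valuation_factor: float = 1.0       # S1/S2 switch valuation of informal care

    # discounting & productivity
    discount_rate: float = 0.03
    base_year: int = 2009
    employment_rate: np.ndarray = None           # (10,) zero from the 65-69 band on
    yearly_earnings: float = 0.0                 # gross + employer share of social contributions
    work_days_lost: np.ndarray = None            # (6,)
    friction_period_years: float = 0.25
    working_days_per_year: float = 250.0
    wage_growth: float = 0.02
    retirement_age: int = 65

    # secular trend on fracture probabilities, (1 + g)^(calendar year - base year)
    trend_rate: float = 0.0

    # provenance tag per parameter name (table1 | table2 | paper_text | placeholder)
    provenance: dict[str, str] = field(default_factory=dict)

    def replace(self, **changes) -> "ParameterInputs":
        return dataclasses.replace(self, **changes)

    def copy(self) -> "ParameterInputs":
        out = dataclasses.replace(self)
        for f in dataclasses.fields(self):
            v = getattr(out, f.name)
            if isinstance(v, np.ndarray):
                setattr(out, f.name, v.copy())
        out.provenance = dict(self.provenance)
        return out

    def placeholders(self) -> list[str]:
        """Names of parameters whose shipped value is a documented placeholder."""
        return sorted(k for k, v in self.provenance.items() if v == "placeholder")


# ---------------------------------------------------------------------------
# Derived parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """Validated, fully derived inputs consumed by the simulation engines.

    Published inputs keep their 5-year-band resolution; all *derived*
    calibration quantities (subgroup prevalences, consistency-split relative
    risks, transition incidences) are resolved per single year of age
    (index = age - 50) so that the prevalence-weighted subgroup identities
    hold at every age the engine visits — the condition under which the
    population-average simulated incidence reproduces the input
    probabilities.
    """

    inputs: ParameterInputs

    p_general: np.ndarray            # (6, 10)
    hospitalization_prob: np.ndarray  # (6,)
    rehab_prob: np.ndarray           # (6,)

    rr_ost: np.ndarray               # (6, 51) osteoporotic vs general population
    rr_noost: np.ndarray             # (6, 51) non-osteoporotic vs general population
    osteo_prevalence: np.ndarray     # (51,) by single year of age
    osteo_incidence: np.ndarray      # (51,) annual onset probability (Podgor–Leske)

    rr_noprev: np.ndarray            # (51,) no-previous-fracture vs general population
    rr_prev_by_type: np.ndarray      # (6,) subsequent-fracture RR given a previous fracture
    prevfx_prevalence: np.ndarray    # (51,) previous-fracture prevalence (forward-solved)

    rr_res_nh: np.ndarray            # (6,) NH residents vs general population
    rr_res_comm: np.ndarray          # (6, 51) community vs general population (derived)
    nh_share: np.ndarray             # (51,) model-consistent NH population share
    nh_admission_prob: np.ndarray    # (6, 10)
    bg_nh_incidence: np.ndarray      # (51,) annual background NH-entry probability
    min_nh_entry_age: int

    all_cause_q: np.ndarray          # (51,)
    rr_fracture_mortality: np.ndarray  # (6, 5, 3)
    rr_mortality_nh: float
    rr_mortality_comm: np.ndarray    # (51,) derived per single year of age

    hospital_cost: np.ndarray
    rehab_cost: np.ndarray
    outpatient_cost: np.ndarray
    home_care_cost: np.ndarray
    informal_care_cost: np.ndarray
    ltc_yearly_cost: float
    informal_valuation_factor: float

    discount_rate: float
    base_year: int
    employment_rate: np.ndarray
    yearly_earnings: float
    work_days_lost: np.ndarray
    friction_period_years: float
    working_days_per_year: float
    wage_growth: float
    retirement_age: int
    trend_rate: float

    def with_discount_rate(self, rate: float) -> "ParameterSet":
        return dataclasses.replace(self, discount_rate=rate)

    # -- engine-facing helpers -------------------------------------------

    def fracture_probability(self, ftype, age, osteoporotic, has_previous, in_nh,
                             trend_factor=1.0):
        """Annual probability of fracture `ftype` for the given risk profile.

        All risk factors combine multiplicatively on the general-population
        probability; the result is clipped to [0, 1].  Works elementwise on
        arrays (the vectorized cohort engine) and on scalars (the per-woman
        engine) alike.
        """
        f = ftype
        ac = age_class_index(age)
        ai = age - AGE_MIN
        p = self.p_general[f, ac] * trend_factor
        p = p * np.where(osteoporotic, self.rr_ost[f, ai], self.rr_noost[f, ai])
        p = p * self.rr_noprev[ai]
        p = p * np.where(has_previous, self.rr_prev_by_type[f], 1.0)
        p = p * np.where(in_nh, self.rr_res_nh[f], self.rr_res_comm[f, ai])
        return np.clip(p, 0.0, 1.0)

    def fracture_mortality_rr(self, ftype: int, age: int, years_since: int) -> float:
        """Excess-mortality RR of one fracture `years_since` model years old.

        Bucket mapping: 0 -> first year, 1-4 -> years 2-5, 5-9 -> years 6-10,
        >= 10 -> no excess (RR 1).
        """
        if years_since >= 10 or years_since < 0:
            return 1.0
        bucket = 0 if years_since == 0 else (1 if years_since < 5 else 2)
        return float(self.rr_fracture_mortality[ftype, mortality_age_class_index(age), bucket])


def build_parameter_set(inputs: ParameterInputs) -> ParameterSet:
    """Validate raw inputs and precompute every derived quantity.

    Validation failures are collected and reported together in a single
    :class:`ParameterError`.
    """
    issues: list[str] = []

    def arr(name, shape) -> np.ndarray:
        v = getattr(inputs, name)
        if v is None:
            issues.append(f"missing table: {name}")
            return np.zeros(shape)
        v = np.asarray(v, dtype=float)
        if v.shape != shape:
            issues.append(f"{name}: expected shape {shape}, got {v.shape}")
            return np.zeros(shape)
        if not np.all(np.isfinite(v)):
            issues.append(f"{name}: contains non-finite values")
        return v

    p_general = arr("p_general", (N_TYPES, N_AGE_CLASSES))
    hosp = arr("hospitalization_prob", (N_TYPES,))
    rehab_p = arr("rehab_prob", (N_TYPES,))
    prev_pf = arr("prev_previous_fx", (N_AGE_CLASSES,))
    gradient = arr("gradient_of_risk", (N_TYPES, N_AGE_CLASSES))
    mean_t = arr("mean_tscore", (N_AGE_CLASSES,))
    care_prev = arr("care_prevalence", (N_AGE_CLASSES,))
    admission = arr("nh_admission_prob", (N_TYPES, N_AGE_CLASSES))
    rr_nh = arr("rr_fracture_nh", (N_TYPES,))
    q = arr("all_cause_q", (AGE_MAX - AGE_MIN + 1,))
    rr_fx_mort = arr("rr_fracture_mortality", (N_TYPES, N_MORTALITY_AGE_CLASSES, 3))
    costs = {n: arr(n, (N_TYPES,)) for n in
             ("hospital_cost", "rehab_cost", "outpatient_cost", "home_care_cost",
              "informal_care_cost", "work_days_lost")}
    emp = arr("employment_rate", (N_AGE_CLASSES,))

    for name, v, lo, hi in (
        ("p_general", p_general, 0.0, 1.0),
        ("hospitalization_prob", hosp, 0.0, 1.0),
        ("rehab_prob", rehab_p, 0.0, 1.0),
        ("prev_previous_fx", prev_pf, 0.0, 1.0),
        ("care_prevalence", care_prev, 0.0, 1.0),
        ("nh_admission_prob", admission, 0.0, 1.0),
        ("all_cause_q", q, 0.0, 1.0),
        ("employment_rate", emp, 0.0, 1.0),
    ):
        if np.any((v < lo) | (v > hi)):
            issues.append(f"{name}: values outside [{lo}, {hi}]")
    for name in ("hospital_cost", "rehab_cost", "outpatient_cost",
                 "home_care_cost", "informal_care_cost"):
        if np.any(costs[name] < 0):
            issues.append(f"{name}: negative unit cost")
    if inputs.ltc_yearly_cost < 0:
        issues.append("ltc_yearly_cost: negative")
    if inputs.discount_rate < 0:
        issues.append("discount_rate: negative")
    if not (hosp[FractureType.HIP] == 1.0 and hosp[FractureType.OTHER_FEMUR] == 1.0):
        issues.append("hip and other_femur hospitalization probabilities must be 1.0 "
                      "(all femoral fractures are treated in an inpatient setting)")
    if np.any(gradient < 1.0):
        issues.append("gradient_of_risk: values < 1")
    if inputs.bmd_threshold >= 0:
        issues.append("bmd_threshold: must be a negative T-score")
    for rr_name in ("rr_any_prev", "rr_hip_prev", "rr_osteo_prev"):
        if getattr(inputs, rr_name) <= 0:
            issues.append(f"{rr_name}: must be > 0")
    if np.any(rr_nh <= 0):
        issues.append("rr_fracture_nh: must be > 0")
    if inputs.rr_mortality_nh <= 0:
        issues.append("rr_mortality_nh: must be > 0")

    # prevalence ladders must be nondecreasing for the irreversible-condition conversion
    if np.any(np.diff(care_prev) < -1e-12):
        issues.append("care_prevalence: must be nondecreasing over age")

    if issues:
        raise ParameterError(issues)

    # ---- derivations ---------------------------------------------------
    # Derived calibration quantities are resolved per single year of age:
    # band-resolution subgroup prevalences drift within a 5-year band and
    # break the prevalence-weighted consistency identities at the ages the
    # engine actually visits.
    n_years = AGE_MAX - AGE_MIN + 1
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    band_midpoints = np.arange(AGE_MIN + 2, AGE_MIN + 2 + 5 * N_AGE_CLASSES, 5, dtype=float)

    def bands_to_years(band_values: np.ndarray) -> np.ndarray:
        """Linear interpolation between band midpoints, flat at the ends."""
        return np.interp(ages, band_midpoints, band_values)

    mean_t_y = bands_to_years(mean_t)
    osteo_prev = norm.cdf(inputs.bmd_threshold - mean_t_y) * inputs.osteo_prevalence_scale
    osteo_prev = np.clip(osteo_prev, 0.0, 0.99)
    if np.any(np.diff(osteo_prev) < -1e-12):
        raise ParameterError(["derived osteoporosis prevalence decreases over age; "
                              "check mean_tscore ladder"])
    osteo_incidence = np.zeros(n_years)
    osteo_incidence[:-1] = prevalence_to_incidence(osteo_prev[:-1], osteo_prev[1:], 1.0)
    osteo_incidence[-1] = osteo_incidence[-2]

    gradient_y = gradient[:, age_class_index(ages.astype(int))]  # bands stay piecewise
    rr_ost = rr_osteoporotic(gradient_y, mean_t_y[np.newaxis, :], inputs.bmd_threshold)
    rr_noost = rr_non_osteoporotic(rr_ost, osteo_prev[np.newaxis, :])

    # previous-fracture prevalence: forward-solved self-consistently — the
    # fraction with a fracture history that the engine itself accumulates
    # when first fractures arrive at rate p_any * rr_noprev (anchored at the
    # published prevalence for the youngest band)
    p_any_band = 1.0 - np.prod(1.0 - p_general, axis=0)  # (10,)
    prevfx_prev = np.zeros(n_years)
    prevfx_prev[0] = prev_pf[0]
    for ai in range(n_years - 1):
        rr_np = 1.0 / (1.0 + (inputs.rr_any_prev - 1.0) * prevfx_prev[ai])
        hazard = 1.0 - np.prod(1.0 - p_general[:, age_class_index(AGE_MIN + ai)] * rr_np)
        prevfx_prev[ai + 1] = prevfx_prev[ai] + (1.0 - prevfx_prev[ai]) * hazard
    rr_noprev = rr_no_previous_fracture(inputs.rr_any_prev, prevfx_prev)
    rr_prev_by_type = np.where(
        np.arange(N_TYPES) == FractureType.HIP, inputs.rr_hip_prev, inputs.rr_osteo_prev
    )

    # nursing-home share: forward-solved under the differential mortality it
    # implies, entering at the background rate that keeps the share on the
    # (interpolated) care-prevalence ladder; the residence splits are then
    # calibrated against this model-consistent share
    care_target = bands_to_years(care_prev)
    nh_share = np.zeros(n_years)
    bg_nh_incidence = np.zeros(n_years)
    rr_mort_comm = np.ones(n_years)
    rr_mnh = float(inputs.rr_mortality_nh)
    for ai in range(n_years):
        s = nh_share[ai]
        if s * rr_mnh >= 1.0:
            raise ParameterError(["nursing-home share * rr_mortality_nh >= 1"])
        rr_mort_comm[ai] = (1.0 - s * rr_mnh) / (1.0 - s) if s > 0 else 1.0
        if ai == n_years - 1:
            break
        qn = min(q[ai] * rr_mnh, 1.0)
        qc = min(q[ai] * rr_mort_comm[ai], 1.0)
        A, B = 1.0 - qn, 1.0 - qc
        tau = care_target[ai + 1]
        e = 0.0
        if AGE_MIN + ai >= inputs.min_nh_entry_age and A > 0.0 and tau > 0.0:
            if tau >= 1.0:
                e = 1.0 - s
            else:
                R = tau * B / ((1.0 - tau) * A)
                e = min(max((R * (1.0 - s) - s) / (1.0 + R), 0.0), 1.0 - s)
        bg_nh_incidence[ai] = e / (1.0 - s) if s < 1.0 else 0.0
        nh_pop = (s + e) * A
        c_pop = (1.0 - s - e) * B
        nh_share[ai + 1] = nh_pop / (nh_pop + c_pop) if nh_pop + c_pop > 0 else s

    share = nh_share[np.newaxis, :]
    if np.any(share * rr_nh[:, np.newaxis] >= 1.0):
        raise ParameterError(["nursing-home share * rr_fracture_nh >= 1: community "
                              "residue risk would be non-positive"])
    rr_res_comm = np.where(share > 0, (1.0 - share * rr_nh[:, np.newaxis]) / (1.0 - share), 1.0)

    placeholders = inputs.placeholders()
    if placeholders:
        log.info("parameter set uses %d placeholder parameter(s): %s",
                 len(placeholders), ", ".join(placeholders))

    return ParameterSet(
        inputs=inputs,
        p_general=p_general,
        hospitalization_prob=hosp,
        rehab_prob=rehab_p,
        rr_ost=rr_ost,
        rr_noost=rr_noost,
        osteo_prevalence=osteo_prev,
        osteo_incidence=osteo_incidence,
        rr_noprev=rr_noprev,
        rr_prev_by_type=rr_prev_by_type,
        prevfx_prevalence=prevfx_prev,
        rr_res_nh=rr_nh,
        rr_res_comm=rr_res_comm,
        nh_share=nh_share,
        nh_admission_prob=admission,
        bg_nh_incidence=bg_nh_incidence,
        min_nh_entry_age=int(inputs.min_nh_entry_age),
        all_cause_q=q,
        rr_fracture_mortality=rr_fx_mort,
        rr_mortality_nh=float(inputs.rr_mortality_nh),
        rr_mortality_comm=rr_mort_comm,
        hospital_cost=costs["hospital_cost"],
        rehab_cost=costs["rehab_cost"],
        outpatient_cost=costs["outpatient_cost"],
        home_care_cost=costs["home_care_cost"],
        informal_care_cost=costs["informal_care_cost"],
        ltc_yearly_cost=float(inputs.ltc_yearly_cost),
        informal_valuation_factor=float(inputs.informal_valuation_factor),
        discount_rate=float(inputs.discount_rate),
        base_year=int(inputs.base_year),
        employment_rate=emp,
        yearly_earnings=float(inputs.yearly_earnings),
        work_days_lost=costs["work_days_lost"],
        friction_period_years=float(inputs.friction_period_years),
        working_days_per_year=float(inputs.working_days_per_year),
        wage_growth=float(inputs.wage_growth),
        retirement_age=int(inputs.retirement_age),
        trend_rate=float(inputs.trend_rate),
    )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("parameter", "fracture_type", "age_class", "bucket",
               "value", "low", "high", "provenance")

#: parameter name -> (inputs attribute, axes) where axes is a subset of
#: {"type", "age", "mort_age_bucket", "single_age"}; scalars have no axes.
_TABLE_LAYOUT: dict[str, tuple[str, tuple[str, ...]]] = {
    "general_fracture_probability": ("p_general", ("type", "age")),
    "hospitalization_probability": ("hospitalization_prob", ("type",)),
    "rehabilitation_probability": ("rehab_prob", ("type",)),
    "previous_fracture_prevalence": ("prev_previous_fx", ("age",)),
    "gradient_of_risk": ("gradient_of_risk", ("type", "age")),
    "mean_tscore": ("mean_tscore", ("age",)),
    "care_prevalence": ("care_prevalence", ("age",)),
    "nh_admission_probability": ("nh_admission_prob", ("type", "age")),
    "rr_fracture_nh": ("rr_fracture_nh", ("type",)),
    "all_cause_mortality": ("all_cause_q", ("single_age",)),
    "rr_fracture_mortality": ("rr_fracture_mortality", ("type", "mort_age", "bucket")),
    "hospital_cost": ("hospital_cost", ("type",)),
    "rehabilitation_cost": ("rehab_cost", ("type",)),
    "outpatient_cost": ("outpatient_cost", ("type",)),
    "home_care_cost": ("home_care_cost", ("type",)),
    "informal_care_cost": ("informal_care_cost", ("type",)),
    "work_days_lost": ("work_days_lost", ("type",)),
    "employment_rate": ("employment_rate", ("age",)),
}

_SCALARS: dict[str, str] = {
    "rr_any_previous": "rr_any_prev",
    "rr_hip_previous": "rr_hip_prev",
    "rr_osteo_previous": "rr_osteo_prev",
    "bmd_threshold": "bmd_threshold",
    "osteo_prevalence_scale": "osteo_prevalence_scale",
    "min_nh_entry_age": "min_nh_entry_age",
    "rr_mortality_nh": "rr_mortality_nh",
    "ltc_yearly_cost": "ltc_yearly_cost",
    "informal_valuation_factor": "informal_valuation_factor",
    "discount_rate": "discount_rate",
    "base_year": "base_year",
    "yearly_earnings": "yearly_earnings",
    "friction_period_years": "friction_period_years",
    "working_days_per_year": "working_days_per_year",
    "wage_growth": "wage_growth",
    "retirement_age": "retirement_age",
    "trend_rate": "trend_rate",
}

#: which output file each parameter is written to
_FILE_OF: dict[str, str] = {
    "general_fracture_probability": "fracture_probabilities.csv",
    "hospitalization_probability": "fracture_probabilities.csv",
    "rehabilitation_probability": "fracture_probabilities.csv",
    "rr_any_previous": "risk_factors.csv",
    "rr_hip_previous": "risk_factors.csv",
    "rr_osteo_previous": "risk_factors.csv",
    "previous_fracture_prevalence": "risk_factors.csv",
    "gradient_of_risk": "risk_factors.csv",
    "mean_tscore": "risk_factors.csv",
    "bmd_threshold": "risk_factors.csv",
    "osteo_prevalence_scale": "risk_factors.csv",
    "care_prevalence": "nursing_home.csv",
    "nh_admission_probability": "nursing_home.csv",
    "rr_fracture_nh": "nursing_home.csv",
    "min_nh_entry_age": "nursing_home.csv",
    "all_cause_mortality": "mortality.csv",
    "rr_fracture_mortality": "mortality.csv",
    "rr_mortality_nh": "mortality.csv",
    "hospital_cost": "costs.csv",
    "rehabilitation_cost": "costs.csv",
    "outpatient_cost": "costs.csv",
    "home_care_cost": "costs.csv",
    "informal_care_cost": "costs.csv",
    "ltc_yearly_cost": "costs.csv",
    "informal_valuation_factor": "costs.csv",
    "discount_rate": "general.csv",
    "base_year": "general.csv",
    "trend_rate": "general.csv",
    "employment_rate": "productivity.csv",
    "yearly_earnings": "productivity.csv",
    "work_days_lost": "productivity.csv",
    "friction_period_years": "productivity.csv",
    "working_days_per_year": "productivity.csv",
    "wage_growth": "productivity.csv",
    "retirement_age": "productivity.csv",
}


def inputs_to_tables(inputs: ParameterInputs) -> pd.DataFrame:
    """Flatten a :class:`ParameterInputs` into the long CSV table format."""
    rows: list[dict] = []

    def prov(name: str) -> str:
        return inputs.provenance.get(name, "placeholder")

    ci_of = {"rr_any_previous": inputs.rr_any_prev_ci,
             "rr_hip_previous": inputs.rr_hip_prev_ci,
             "rr_osteo_previous": inputs.rr_osteo_prev_ci}

    for pname, (attr, axes) in _TABLE_LAYOUT.items():
        v = np.asarray(getattr(inputs, attr), dtype=float)
        if axes == ("type", "age"):
            lo = getattr(inputs, "gradient_low") if pname == "gradient_of_risk" else None
            hi = getattr(inputs, "gradient_high") if pname == "gradient_of_risk" else None
            for f in FractureType:
                for a, lab in enumerate(AGE_CLASS_LABELS):
                    rows.append(dict(parameter=pname, fracture_type=f.label, age_class=lab,
                                     bucket="", value=v[f, a],
                                     low="" if lo is None else lo[f, a],
                                     high="" if hi is None else hi[f, a],
                                     provenance=prov(pname)))
        elif axes == ("type",):
            for f in FractureType:
                rows.append(dict(parameter=pname, fracture_type=f.label, age_class="",
                                 bucket="", value=v[f], low="", high="", provenance=prov(pname)))
        elif axes == ("age",):
            for a, lab in enumerate(AGE_CLASS_LABELS):
                rows.append(dict(parameter=pname, fracture_type="", age_class=lab,
                                 bucket="", value=v[a], low="", high="", provenance=prov(pname)))
        elif axes == ("single_age",):
            for i, age in enumerate(range(AGE_MIN, AGE_MAX + 1)):
                rows.append(dict(parameter=pname, fracture_type="", age_class=str(age),
                                 bucket="", value=v[i], low="", high="", provenance=prov(pname)))
        elif axes == ("type", "mort_age", "bucket"):
            for f in FractureType:
                for a, lab in enumerate(MORTALITY_AGE_CLASS_LABELS):
                    for b, blab in enumerate(MORTALITY_BUCKET_LABELS):
                        rows.append(dict(parameter=pname, fracture_type=f.label,
                                         age_class=lab, bucket=blab, value=v[f, a, b],
                                         low="", high="", provenance=prov(pname)))

    for pname, attr in _SCALARS.items():
        lo, hi = ci_of.get(pname, ("", ""))
        rows.append(dict(parameter=pname, fracture_type="", age_class="", bucket="",
                         value=float(getattr(inputs, attr)), low=lo, high=hi,
                         provenance=prov(pname)))

    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_parameter_tables(inputs: ParameterInputs, out_dir) -> list[Path]:
    """Write the parameter tables as a directory of UTF-8 CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = inputs_to_tables(inputs)
    df["file"] = df["parameter"].map(_FILE_OF)
    written = []
    for fname, chunk in df.groupby("file", sort=True):
        path = out_dir / fname
        chunk[list(CSV_COLUMNS)].to_csv(path, index=False, encoding="utf-8")
        written.append(path)
    return written


def _ftype_index(label: str) -> int:
    return FractureType[label.upper()].value


def tables_to_inputs(df: pd.DataFrame) -> ParameterInputs:
    """Rebuild :class:`ParameterInputs` from the long CSV table format."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError([f"missing CSV column(s): {', '.join(missing)}"])
    df = df.fillna("")
    inputs = ParameterInputs()
    provenance: dict[str, str] = {}
    age_idx = {lab: i for i, lab in enumerate(AGE_CLASS_LABELS)}
    mort_idx = {lab: i for i, lab in enumerate(MORTALITY_AGE_CLASS_LABELS)}
    bucket_idx = {lab: i for i, lab in enumerate(MORTALITY_BUCKET_LABELS)}

    issues: list[str] = []
    grouped = dict(tuple(df.groupby("parameter")))
    known = set(_TABLE_LAYOUT) | set(_SCALARS)
    for pname in grouped:
        if pname not in known:
            issues.append(f"unknown parameter in tables: {pname}")
    for pname, (attr, axes) in _TABLE_LAYOUT.items():
        if pname not in grouped:
            issues.append(f"missing parameter table: {pname}")
            continue
        chunk = grouped[pname]
        provenance[pname] = str(chunk["provenance"].iloc[0])
        try:
            if axes == ("type", "age"):
                v = np.full((N_TYPES, N_AGE_CLASSES), np.nan)
                lo = np.full_like(v, np.nan)
                hi = np.full_like(v, np.nan)
                for _, r in chunk.iterrows():
                    f, a = _ftype_index(r.fracture_type), age_idx[r.age_class]
                    v[f, a] = float(r.value)
                    if r.low != "":
                        lo[f, a] = float(r.low)
                    if r.high != "":
                        hi[f, a] = float(r.high)
                setattr(inputs, attr, v)
                if pname == "gradient_of_risk" and not np.any(np.isnan(lo)):
                    inputs.gradient_low, inputs.gradient_high = lo, hi
            elif axes == ("type",):
                v = np.full(N_TYPES, np.nan)
                for _, r in chunk.iterrows():
                    v[_ftype_index(r.fracture_type)] = float(r.value)
                setattr(inputs, attr, v)
            elif axes == ("age",):
                v = np.full(N_AGE_CLASSES, np.nan)
                for _, r in chunk.iterrows():
                    v[age_idx[r.age_class]] = float(r.value)
                setattr(inputs, attr, v)
            elif axes == ("single_age",):
                v = np.full(AGE_MAX - AGE_MIN + 1, np.nan)
                for _, r in chunk.iterrows():
                    v[int(r.age_class) - AGE_MIN] = float(r.value)
                setattr(inputs, attr, v)
            elif axes == ("type", "mort_age", "bucket"):
                v = np.full((N_TYPES, N_MORTALITY_AGE_CLASSES, 3), np.nan)
                for _, r in chunk.iterrows():
                    v[_ftype_index(r.fracture_type), mort_idx[r.age_class],
                      bucket_idx[str(r.bucket)]] = float(r.value)
                setattr(inputs, attr, v)
            if np.any(np.isnan(np.asarray(getattr(inputs, attr), dtype=float))):
                issues.append(f"{pname}: incomplete table (missing cells)")
        except (KeyError, ValueError) as exc:
            issues.append(f"{pname}: malformed row ({exc})")

    for pname, attr in _SCALARS.items():
        if pname not in grouped:
            issues.append(f"missing scalar parameter: {pname}")
            continue
        r = grouped[pname].iloc[0]
        provenance[pname] = str(r.provenance)
        val = float(r.value)
        if attr in ("min_nh_entry_age", "base_year", "retirement_age"):
            setattr(inputs, attr, int(val))
        else:
            setattr(inputs, attr, val)
        if pname == "rr_any_previous" and r.low != "":
            inputs.rr_any_prev_ci = (float(r.low), float(r.high))
        if pname == "rr_hip_previous" and r.low != "":
            inputs.rr_hip_prev_ci = (float(r.low), float(r.high))
        if pname == "rr_osteo_previous" and r.low != "":
            inputs.rr_osteo_prev_ci = (float(r.low), float(r.high))

    if issues:
        raise ParameterError(issues)
    inputs.provenance = provenance
    return inputs


def load_parameter_tables(param_dir) -> ParameterInputs:
    """Read every ``*.csv`` in a parameter directory (strict headers, UTF-8)."""
    param_dir = Path(param_dir)
    paths = sorted(param_dir.glob("*.csv"))
    if not paths:
        raise ParameterError([f"no CSV parameter tables found in {param_dir}"])
    frames = []
    for path in paths:
        chunk = pd.read_csv(path, encoding="utf-8", dtype=str, keep_default_na=False)
        if tuple(chunk.columns) != CSV_COLUMNS:
            raise ParameterError(
                [f"{path.name}: expected header {','.join(CSV_COLUMNS)}, "
                 f"got {','.join(chunk.columns)}"]
            )
        frames.append(chunk)
    return tables_to_inputs(pd.concat(frames, ignore_index=True))


def load_parameter_set(param_dir) -> ParameterSet:
    return build_parameter_set(load_parameter_tables(param_dir))
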