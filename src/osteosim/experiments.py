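"""The analysis layer: base case, scenarios, sensitivity analyses, PSA, validation.

Every experiment is a pure function of (parameters, seed).  Excess
quantities — the burden attributable to osteoporosis — are estimated by
simulating an average-osteoporosis-risk cohort and a never-osteoporosis
cohort on identical random streams (common random numbers) and differencing,
so first-order Monte Carlo noise cancels exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortResult, run_cohort
from .costs import CohortSummary, ExcessSummary, aggregate, compute_costs, excess
from .engine import BASE_CASE, ScenarioSpec, enumerate_scenarios
from .parameters import (
    AGE_CLASS_LABELS,
    FractureType,
    N_TYPES,
    ParameterInputs,
    ParameterSet,
    build_parameter_set,
)

# ---------------------------------------------------------------------------
# Base case
# ---------------------------------------------------------------------------


@dataclass
class BaseCaseResult:
    average: CohortSummary
    never: CohortSummary
    excess: ExcessSummary
    average_cohort: CohortResult
    never_cohort: CohortResult


def run_paired(params: ParameterSet, scenario: ScenarioSpec, n: int, seed: int,
               discount_rate: float | None = None) -> BaseCaseResult:
    """Simulate a scenario and its never-osteoporosis twin on shared streams."""
    never_scenario = dataclasses.replace(scenario, disease="nO")
    res_a = run_cohort(scenario, params, n, seed)
    res_n = run_cohort(never_scenario, params, n, seed)
    sum_a = aggregate(res_a, compute_costs(res_a, params, discount_rate))
    sum_n = aggregate(res_n, compute_costs(res_n, params, discount_rate))
    return BaseCaseResult(average=sum_a, never=sum_n, excess=excess(sum_a, sum_n),
                          average_cohort=res_a, never_cohort=res_n)


def run_base_case(params: ParameterSet, n: int = 200_000, seed: int = 0) -> BaseCaseResult:
    """The headline estimate: lifetime fractures and costs of a 50 year old
    woman at average osteoporosis risk, her never-osteoporosis counterpart,
    and the osteoporosis-attributable excess."""
    return run_paired(params, BASE_CASE, n, seed)


# ---------------------------------------------------------------------------
# Scenario analysis
# ---------------------------------------------------------------------------


def run_scenarios(params: ParameterSet, n: int = 200_000, seed: int = 0) -> pd.DataFrame:
    """Direct lifetime fracture costs for the 18 start-characteristic scenarios."""
    rows = []
    for sc in enumerate_scenarios():
        res = run_cohort(sc, params, n, seed)
        summary = aggregate(res, compute_costs(res, params))
        rows.append({
            "scenario": sc.label,
            "start_age": sc.start_age,
            "residence": sc.residence,
            "disease": sc.disease,
            "history": sc.history,
            "direct_cost_undiscounted": summary.total_direct["undiscounted"],
            "direct_cost_discounted": summary.total_direct["discounted"],
        })
    return pd.DataFrame(rows).set_index("scenario")


# ---------------------------------------------------------------------------
# Deterministic sensitivity analyses S1-S20
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivitySpec:
    """A declarative one-way parameter transformation (S1..S20)."""

    identifier: str
    description: str
    transform: Callable[[ParameterInputs], ParameterInputs]
    discount_rate: float | None = None  # overrides the cost-engine rate only

    def apply(self, inputs: ParameterInputs) -> ParameterSet:
        return build_parameter_set(self.transform(inputs.copy()))


def _t(fn):
    return fn


def _no_excess_mortality(i: ParameterInputs) -> ParameterInputs:
    i.rr_fracture_mortality = np.ones_like(i.rr_fracture_mortality)
    return i


def _first_year_only(i: ParameterInputs) -> ParameterInputs:
    i.rr_fracture_mortality[:, :, 1:] = 1.0
    return i


def _first_year_30pct(i: ParameterInputs) -> ParameterInputs:
    i.rr_fracture_mortality[:, :, 0] = 1.0 + 0.3 * (i.rr_fracture_mortality[:, :, 0] - 1.0)
    i.rr_fracture_mortality[:, :, 1:] = 1.0
    return i


def _no_prevfx(i: ParameterInputs) -> ParameterInputs:
    # drop the risk elevation of a fracture history but keep the calibrated
    # no-previous-fracture probabilities as the baseline (a full
    # recalibration would make this analysis a no-op)
    i.rr_hip_prev = i.rr_osteo_prev = 1.0
    return i


def _prevfx_ci(which: int):
    def fn(i: ParameterInputs) -> ParameterInputs:
        i.rr_any_prev = i.rr_any_prev_ci[which]
        i.rr_hip_prev = i.rr_hip_prev_ci[which]
        i.rr_osteo_prev = i.rr_osteo_prev_ci[which]
        return i
    return fn


def _gradient_ci(which: str):
    def fn(i: ParameterInputs) -> ParameterInputs:
        i.gradient_of_risk = np.maximum(
            i.gradient_low if which == "low" else i.gradient_high, 1.0).copy()
        return i
    return fn


def _prevalence_scale(factor: float):
    def fn(i: ParameterInputs) -> ParameterInputs:
        i.osteo_prevalence_scale = factor
        return i
    return fn


def _probability_scale(factor: float):
    def fn(i: ParameterInputs) -> ParameterInputs:
        i.p_general = np.clip(i.p_general * factor, 0.0, 1.0)
        return i
    return fn


def _hip_only_nh(i: ParameterInputs) -> ParameterInputs:
    mask = np.zeros(N_TYPES, dtype=bool)
    mask[FractureType.HIP] = True
    i.nh_admission_prob = np.where(mask[:, np.newaxis], i.nh_admission_prob, 0.0)
    return i


def _trend(rate: float):
    def fn(i: ParameterInputs) -> ParameterInputs:
        i.trend_rate = rate
        return i
    return fn


def _informal_factor(factor: float):
    def fn(i: ParameterInputs) -> ParameterInputs:
        i.informal_valuation_factor = factor
        return i
    return fn


SENSITIVITY_SPECS: dict[str, SensitivitySpec] = {s.identifier: s for s in [
    SensitivitySpec("S1", "informal care valued by the opportunity-cost approach "
                    "(average hourly wage)", _informal_factor(1.40)),
    SensitivitySpec("S2", "informal care valued at the 2010 care-sector minimum wage",
                    _informal_factor(0.70)),
    SensitivitySpec("S3", "no excess mortality due to fractures", _no_excess_mortality),
    SensitivitySpec("S4", "fracture excess mortality in the first year only", _first_year_only),
    SensitivitySpec("S5", "30% of first-year excess mortality, none thereafter",
                    _first_year_30pct),
    SensitivitySpec("S6", "previous fracture not a risk factor", _no_prevfx),
    SensitivitySpec("S7", "lower 95% CI of the previous-fracture relative risks",
                    _prevfx_ci(0)),
    SensitivitySpec("S8", "upper 95% CI of the previous-fracture relative risks",
                    _prevfx_ci(1)),
    SensitivitySpec("S9", "lower value of the BMD gradients of risk", _gradient_ci("low")),
    SensitivitySpec("S10", "upper value of the BMD gradients of risk", _gradient_ci("high")),
    SensitivitySpec("S11", "osteoporosis prevalence +30%", _prevalence_scale(1.3)),
    SensitivitySpec("S12", "osteoporosis prevalence -30%", _prevalence_scale(0.7)),
    SensitivitySpec("S13", "all input fracture probabilities +30%", _probability_scale(1.3)),
    SensitivitySpec("S14", "all input fracture probabilities -30%", _probability_scale(0.7)),
    SensitivitySpec("S15", "only hip fractures trigger NH institutionalization",
                    _hip_only_nh),
    SensitivitySpec("S16", "fracture incidence trend +1% per year", _trend(0.01)),
    SensitivitySpec("S17", "fracture incidence trend -1% per year", _trend(-0.01)),
    SensitivitySpec("S18", "fracture incidence trend +2% per year", _trend(0.02)),
    SensitivitySpec("S19", "fracture incidence trend -2% per year", _trend(-0.02)),
    SensitivitySpec("S20", "discount rate 5%", _t(lambda i: i), discount_rate=0.05),
]}


def run_sensitivity(params: ParameterSet, ids: Sequence[str] | None = None,
                    n: int = 200_000, seed: int = 0) -> pd.DataFrame:
    """Percentage change of discounted direct excess costs vs the base case.

    Each spec is applied to a fresh copy of the raw inputs, rebuilt (so the
    calibration identities are re-derived), and run on the *same* random
    streams as the base case, so the reported percentages are free of
    first-order simulation noise.
    """
    ids = list(SENSITIVITY_SPECS) if ids is None else list(ids)
    base = run_base_case(params, n=n, seed=seed)
    base_excess = base.excess.total_direct["discounted"]
    rows = []
    for sid in ids:
        spec = SENSITIVITY_SPECS[sid]
        p_s = spec.apply(params.inputs)
        res = run_paired(p_s, BASE_CASE, n, seed, discount_rate=spec.discount_rate)
        ex = res.excess.total_direct["discounted"]
        rows.append({
            "id": sid,
            "description": spec.description,
            "excess_direct_discounted": ex,
            "pct_change": 100.0 * (ex - base_excess) / base_excess if base_excess else np.nan,
        })
    return pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaSpec:
    """Second-order uncertainty settings.

    Distribution families: beta for probabilities and prevalences, gamma for
    unit costs, lognormal for relative risks — each moment-matched to the
    point value (mean) and to the shipped 95% CI where available, otherwise
    to a coefficient of variation.
    """

    m: int = 1_500              # outer parameter draws
    n: int = 10_000             # women per risk group per draw
    cv: float = 0.2             # default spread where no CI is shipped
    use_ci: bool = True         # shipped 95% CIs override cv where available
    percentiles: tuple[float, float] = (2.5, 97.5)


def _beta_like(rng: np.random.Generator, mean, cv: float):
    """Beta draw with the given mean and sd = cv * mean (elementwise)."""
    mean = np.asarray(mean, dtype=float)
    if cv < 1e-6:
        return mean.copy() if mean.ndim else float(mean)
    out = mean.copy()
    ok = (mean > 0) & (mean < 1)
    m = mean[ok]
    var = np.minimum((cv * m) ** 2, 0.9 * m * (1 - m))
    nu = m * (1 - m) / var - 1.0
    out[ok] = rng.beta(m * nu, (1 - m) * nu)
    return out if out.ndim else float(out)


def _gamma_like(rng: np.random.Generator, mean, cv: float):
    mean = np.asarray(mean, dtype=float)
    if cv < 1e-6:
        return mean.copy() if mean.ndim else float(mean)
    out = mean.copy()
    ok = mean > 0
    shape = 1.0 / cv**2
    out[ok] = rng.gamma(shape, mean[ok] / shape)
    return out if out.ndim else float(out)


def _lognormal_rr(rng: np.random.Generator, point, ci=None, cv: float = 0.2):
    """Lognormal RR draw; sigma from the 95% CI when shipped, else from cv."""
    point = np.asarray(point, dtype=float)
    if cv < 1e-6 and ci is None:
        return point.copy() if point.ndim else float(point)
    if ci is not None and ci[0] > 0 and ci[1] > ci[0]:
        sigma = (np.log(ci[1]) - np.log(ci[0])) / (2 * 1.959963984540054)
    else:
        sigma = np.sqrt(np.log(1 + cv**2))
    out = np.where(point > 1.0,  # RRs of exactly 1 stay degenerate
                   np.exp(np.log(np.maximum(point, 1e-12)) + sigma * rng.standard_normal(point.shape if point.ndim else None)),
                   point)
    return out if np.ndim(out) else float(out)


def sample_parameters(inputs: ParameterInputs, rng: np.random.Generator,
                      spec: PsaSpec, max_attempts: int = 200) -> ParameterInputs:
    """One second-order parameter draw (moment-matched families per class).

    Draws are truncated to the feasible region: a draw whose joint values
    violate a consistency constraint (e.g. prevalence x RR >= 1) is
    rejected and redrawn, so every returned input set validates.
    """
    for _ in range(max_attempts):
        candidate = _sample_once(inputs, rng, spec)
        try:
            build_parameter_set(candidate)
        except Exception:
            continue
        return candidate
    raise RuntimeError("could not draw a consistent parameter set; "
                       "check the PSA spread settings")


def _sample_once(inputs: ParameterInputs, rng: np.random.Generator,
                 spec: PsaSpec) -> ParameterInputs:
    i = inputs.copy()
    cv = spec.cv
    i.p_general = np.clip(_beta_like(rng, i.p_general, cv), 0, 1)
    i.rehab_prob = np.clip(_beta_like(rng, i.rehab_prob, cv), 0, 1)
    non_fixed = i.hospitalization_prob < 1.0
    hp = _beta_like(rng, i.hospitalization_prob, cv)
    i.hospitalization_prob = np.where(non_fixed, np.clip(hp, 0.01, 1.0),
                                      i.hospitalization_prob)
    common_pf = float(_beta_like(rng, np.asarray(0.5), cv)) / 0.5
    i.prev_previous_fx = np.clip(i.prev_previous_fx * common_pf, 0, 0.95)
    i.nh_admission_prob = np.clip(_beta_like(rng, i.nh_admission_prob, cv), 0, 1)
    common_care = float(_beta_like(rng, np.asarray(0.5), cv)) / 0.5
    i.care_prevalence = np.clip(i.care_prevalence * common_care, 0, 0.6)
    i.osteo_prevalence_scale = float(np.clip(_beta_like(rng, np.asarray(0.5), cv) / 0.5,
                                             0.3, 1.9))

    ci = (lambda c: c if spec.use_ci else None)
    i.rr_any_prev = _lognormal_rr(rng, i.rr_any_prev, ci(i.rr_any_prev_ci), cv)
    i.rr_hip_prev = _lognormal_rr(rng, i.rr_hip_prev, ci(i.rr_hip_prev_ci), cv)
    i.rr_osteo_prev = _lognormal_rr(rng, i.rr_osteo_prev, ci(i.rr_osteo_prev_ci), cv)
    g = _lognormal_rr(rng, i.gradient_of_risk, cv=cv)
    i.gradient_of_risk = np.maximum(g, 1.0)
    i.rr_fracture_nh = np.maximum(_lognormal_rr(rng, i.rr_fracture_nh, cv=cv), 0.1)
    i.rr_fracture_mortality = np.maximum(
        _lognormal_rr(rng, i.rr_fracture_mortality, cv=cv), 1.0)
    i.rr_mortality_nh = float(np.clip(_lognormal_rr(rng, np.asarray(i.rr_mortality_nh),
                                                    cv=cv), 1.0, 2.6))

    for attr in ("hospital_cost", "rehab_cost", "outpatient_cost",
                 "home_care_cost", "informal_care_cost"):
        setattr(i, attr, _gamma_like(rng, getattr(i, attr), cv))
    i.ltc_yearly_cost = float(_gamma_like(rng, np.asarray(i.ltc_yearly_cost), cv))
    return i


@dataclass
class PsaResult:
    draws: pd.DataFrame       # one row per parameter draw
    intervals: pd.DataFrame   # 2.5/97.5 percentiles (and mean) per quantity


def run_psa(params: ParameterSet, spec: PsaSpec | None = None, seed: int = 0) -> PsaResult:
    """Second-order uncertainty: m parameter draws, each with paired CRN runs.

    The simulation streams are held fixed across draws (same seed), so the
    spread of the outputs reflects parameter uncertainty, not resampling of
    the women.
    """
    spec = spec or PsaSpec()
    prng = np.random.default_rng(seed)
    rows = []
    for rep in range(spec.m):
        p_s = build_parameter_set(sample_parameters(params.inputs, prng, spec))
        res = run_paired(p_s, BASE_CASE, spec.n, seed)
        row = {"rep": rep}
        for tag, s in (("average", res.average), ("never", res.never)):
            row[f"{tag}_direct_discounted"] = s.total_direct["discounted"]
            row[f"{tag}_direct_undiscounted"] = s.total_direct["undiscounted"]
            for f in FractureType:
                row[f"{tag}_count_{f.label}"] = s.mean_counts[f.label]
        row["excess_direct_discounted"] = res.excess.total_direct["discounted"]
        row["excess_direct_undiscounted"] = res.excess.total_direct["undiscounted"]
        for f in FractureType:
            row[f"excess_count_{f.label}"] = res.excess.mean_counts[f.label]
        rows.append(row)
    draws = pd.DataFrame(rows).set_index("rep")
    lo, hi = spec.percentiles
    intervals = pd.DataFrame({
        "mean": draws.mean(),
        f"p{lo}": draws.quantile(lo / 100.0),
        f"p{hi}": draws.quantile(hi / 100.0),
    })
    return PsaResult(draws=draws, intervals=intervals)


# ---------------------------------------------------------------------------
# Internal validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationResult:
    rates: pd.DataFrame               # expected vs modeled incidence per age class x type
    count_distribution: pd.DataFrame  # share of women with 0..6+ fractures per type

    def modeled_rate(self, fracture_type: str, age_class: str) -> float:
        sel = self.rates[(self.rates["fracture_type"] == fracture_type)
                         & (self.rates["age_class"] == age_class)]
        return float(sel["modeled"].iloc[0])


def internal_validation(params: ParameterSet, n: int = 200_000, seed: int = 0,
                        cohort: CohortResult | None = None) -> ValidationResult:
    """Compare modeled age-class incidence in the average-risk population
    with the general-population input probabilities.

    With correctly calibrated subgroup relative risks, the population-average
    modeled incidence converges to the inputs as n grows; this is the
    model's internal consistency check.
    """
    res = cohort if cohort is not None else run_cohort(BASE_CASE, params, n, seed)
    py = res.person_years_by_age_class()
    fx = res.fractures_by_age_class()
    rows = []
    for a, lab in enumerate(AGE_CLASS_LABELS):
        for f in FractureType:
            modeled = fx[a, f] / py[a] if py[a] > 0 else np.nan
            rows.append({
                "age_class": lab, "fracture_type": f.label,
                "expected": params.p_general[f, a], "modeled": modeled,
                "person_years": py[a], "fractures": fx[a, f],
            })
    rates = pd.DataFrame(rows)
    costs_free = aggregate(res, compute_costs(res, params))
    return ValidationResult(rates=rates, count_distribution=costs_free.count_distribution)
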