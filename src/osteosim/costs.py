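"""Cost attachment, long-term-care attribution, productivity losses, discounting.

Costs are booked at the end of the interval in which the triggering event
occurs and discounted to the 2009 base year with a whole-year exponent;
the two stream-like categories named for half-cycle correction — long-term
care and mortality-related productivity — weight their first year by 0.5.
"Direct" costs comprise the first six sectors; the two productivity sectors
(human capital and friction cost valuations of the same losses) are carried
separately and never enter direct totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import NH_CAUSE_FRACTURE, CohortResult
from .parameters import N_TYPES, FractureType, ParameterSet, age_class_index

SECTORS = (
    "hospital",
    "rehabilitation",
    "long_term_care",
    "outpatient",
    "professional_home_care",
    "informal_care",
    "productivity_hca",
    "productivity_fca",
)
DIRECT_SECTORS = SECTORS[:6]
N_SECTORS = len(SECTORS)
_SEC = {s: i for i, s in enumerate(SECTORS)}


def discount(amount, model_year, rate: float, base_year: int = 2009):
    """Present value at the base year: amount / (1 + rate)^(model_year - base_year)."""
    t = np.asarray(model_year) - base_year
    if np.any(t < 0):
        raise ValueError("cannot discount to a base year after the cash flow")
    out = np.asarray(amount, dtype=float) / (1.0 + rate) ** t
    return out if out.ndim else float(out)


@dataclass
class CohortCosts:
    """Per-woman and per-stratum cost ledgers of one simulated cohort."""

    per_person: np.ndarray          # (n, 8) undiscounted EUR by sector
    per_person_disc: np.ndarray     # (n, 8) discounted EUR by sector
    by_type: np.ndarray             # (6, 8) totals by triggering fracture type (LTC column 0)
    by_type_disc: np.ndarray
    by_year_direct: np.ndarray      # (T,) undiscounted direct totals per interval
    discount_rate: float

    def per_capita(self, discounted: bool) -> dict[str, float]:
        m = self.per_person_disc if discounted else self.per_person
        n = m.shape[0]
        return {s: float(m[:, i].sum()) / n for i, s in enumerate(SECTORS)}

    def total_direct(self, discounted: bool) -> float:
        m = self.per_person_disc if discounted else self.per_person
        return float(m[:, :6].sum()) / m.shape[0]


def acute_fracture_costs(ftype: int, hospitalized: bool, rehab: bool, age: int,
                         in_nh: bool, params: ParameterSet) -> dict[str, float]:
    """Unit costs triggered by a single acute fracture (undiscounted EUR).

    Hospitalized fractures accrue the hospital figure (which bundles
    post-hospital outpatient aftercare) plus rehabilitation when drawn;
    fractures treated exclusively in the outpatient sector accrue the
    outpatient figure.  Professional home care and informal care apply only
    to community-dwelling women older than 65.
    """
    f = int(ftype)
    out = {s: 0.0 for s in SECTORS}
    if hospitalized:
        out["hospital"] = float(params.hospital_cost[f])
        if rehab:
            out["rehabilitation"] = float(params.rehab_cost[f])
    else:
        out["outpatient"] = float(params.outpatient_cost[f])
    if age > 65 and not in_nh:
        out["professional_home_care"] = float(params.home_care_cost[f])
        out["informal_care"] = float(params.informal_care_cost[f]
                                     * params.informal_valuation_factor)
    return out


def ltc_attribution_years(entry_year: int, cf_entry_year: int, last_alive_year: int) -> float:
    """Fracture-attributable nursing-home years (entry year counts one half).

    Attribution covers the years from the fracture-caused NH entry up to the
    final year alive, and stops permanently once the counterfactual
    background track would have institutionalized the woman anyway.
    """
    stop = min(cf_entry_year - 1, last_alive_year)
    if stop < entry_year:
        return 0.0
    return (stop - entry_year + 1) - 0.5


def compute_costs(result: CohortResult, params: ParameterSet,
                  discount_rate: float | None = None) -> CohortCosts:
    """Attach all unit costs to a simulated cohort (vectorized)."""
    r = params.discount_rate if discount_rate is None else discount_rate
    n, T = result.n, result.n_years
    start = result.start_age
    pp = np.zeros((n, N_SECTORS))
    ppd = np.zeros((n, N_SECTORS))
    by_type = np.zeros((N_TYPES, N_SECTORS))
    by_type_d = np.zeros((N_TYPES, N_SECTORS))
    by_year = np.zeros(T)

    v = 1.0 / (1.0 + r)
    disc_t = v ** np.arange(T)

    # ---- acute event costs --------------------------------------------
    ev = result.events
    if len(ev):
        age = start + ev.year
        dfac = disc_t[ev.year]
        community = result.nh_entry_year[ev.person] >= ev.year  # entry this year: still community rules
        care_ok = (age > 65) & community

        amounts = {
            "hospital": np.where(ev.hospitalized, params.hospital_cost[ev.ftype], 0.0),
            "rehabilitation": np.where(ev.rehab, params.rehab_cost[ev.ftype], 0.0),
            "outpatient": np.where(~ev.hospitalized, params.outpatient_cost[ev.ftype], 0.0),
            "professional_home_care": np.where(care_ok, params.home_care_cost[ev.ftype], 0.0),
            "informal_care": np.where(care_ok, params.informal_care_cost[ev.ftype]
                                      * params.informal_valuation_factor, 0.0),
        }
        for sector, amt in amounts.items():
            s = _SEC[sector]
            np.add.at(pp[:, s], ev.person, amt)
            np.add.at(ppd[:, s], ev.person, amt * dfac)
            np.add.at(by_type[:, s], ev.ftype, amt)
            np.add.at(by_type_d[:, s], ev.ftype, amt * dfac)
            np.add.at(by_year, ev.year, amt)

    # ---- fracture-attributable long-term care -------------------------
    # yearly NH cost while the entry is fracture-caused and the parallel
    # background track has not yet caught up; entry year weighted 0.5
    ltc_mask = result.nh_cause == NH_CAUSE_FRACTURE
    if ltc_mask.any():
        idx = np.nonzero(ltc_mask)[0]
        entry = result.nh_entry_year[idx]
        stop = np.minimum(result.cf_entry_year[idx] - 1, result.last_alive_year()[idx])
        C = params.ltc_yearly_cost
        s = _SEC["long_term_care"]
        for t in range(T):
            w = np.where((entry <= t) & (t <= stop), np.where(entry == t, 0.5, 1.0), 0.0)
            if not w.any():
                continue
            amt = C * w
            pp[idx, s] += amt
            ppd[idx, s] += amt * disc_t[t]
            by_year[t] += amt.sum()

    # ---- productivity: fracture-related work absence ------------------
    ret = params.retirement_age
    wd = params.working_days_per_year
    friction_days = params.friction_period_years * wd
    if len(ev):
        age = start + ev.year
        working = age < ret
        emp = params.employment_rate[age_class_index(np.minimum(age, 100))]
        daily = params.yearly_earnings * (1 + params.wage_growth) ** ev.year / wd
        days = params.work_days_lost[ev.ftype]
        hca = np.where(working, emp * daily * days, 0.0)
        fca = np.where(working, emp * daily * np.minimum(days, friction_days), 0.0)
        dfac = disc_t[ev.year]
        for sector, amt in (("productivity_hca", hca), ("productivity_fca", fca)):
            s = _SEC[sector]
            np.add.at(pp[:, s], ev.person, amt)
            np.add.at(ppd[:, s], ev.person, amt * dfac)
            np.add.at(by_type[:, s], ev.ftype, amt)
            np.add.at(by_type_d[:, s], ev.ftype, amt * dfac)

    # ---- productivity: fracture-related premature death ----------------
    # human capital: discounted earnings stream to retirement, first year 0.5
    # friction cost: one friction period of earnings at the year of death
    sh, sf = _SEC["productivity_hca"], _SEC["productivity_fca"]
    for t in range(T):
        age_d = start + t
        if age_d >= ret:
            break
        sel = np.nonzero(result.fracture_related_death & (result.death_year == t))[0]
        if sel.size == 0:
            continue
        for k in range(ret - age_d):
            w = 0.5 if k == 0 else 1.0
            yr = t + k
            val = (params.employment_rate[age_class_index(age_d + k)]
                   * params.yearly_earnings * (1 + params.wage_growth) ** yr * w)
            pp[sel, sh] += val
            ppd[sel, sh] += val * v ** yr
        fval = (params.employment_rate[age_class_index(age_d)]
                * params.yearly_earnings * (1 + params.wage_growth) ** t
                * params.friction_period_years)
        pp[sel, sf] += fval
        ppd[sel, sf] += fval * disc_t[t]

    return CohortCosts(per_person=pp, per_person_disc=ppd,
                       by_type=by_type, by_type_disc=by_type_d,
                       by_year_direct=by_year, discount_rate=r)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Per-capita lifetime outcomes of one simulated cohort."""

    label: str
    n: int
    mean_counts: dict[str, float]               # lifetime fractures per woman, by type
    count_distribution: pd.DataFrame            # share of women with 0..6+ fractures, by type
    sector_costs: pd.DataFrame                  # per-capita EUR by sector x {undiscounted, discounted}
    by_type_costs: pd.DataFrame                 # per-capita direct EUR excl. LTC, by fracture type
    total_direct: dict[str, float]              # {"undiscounted": .., "discounted": ..} incl. LTC
    annual_direct_per_capita: pd.DataFrame      # undiscounted EUR per woman alive, by age

    def sector_shares(self, discounted: bool = True) -> dict[str, float]:
        col = "discounted" if discounted else "undiscounted"
        tot = self.total_direct[col]
        direct = self.sector_costs.loc[list(DIRECT_SECTORS), col]
        return {} if tot == 0 else (100.0 * direct / tot).to_dict()


def aggregate(result: CohortResult, costs: CohortCosts) -> CohortSummary:
    """Collapse a cohort into the per-capita summary (count and cost tables)."""
    if result.n == 0:
        raise ValueError("empty cohort")
    n = result.n
    mean_counts = {f.label: float(result.counts[:, f].sum()) / n for f in FractureType}

    dist = np.zeros((N_TYPES, 7))
    capped = np.minimum(result.counts, 6)
    for f in range(N_TYPES):
        dist[f] = np.bincount(capped[:, f], minlength=7)[:7] / n
    count_distribution = pd.DataFrame(
        dist, index=[f.label for f in FractureType],
        columns=[str(k) for k in range(6)] + ["6+"])

    sector_costs = pd.DataFrame(
        {"undiscounted": [costs.per_person[:, i].sum() / n for i in range(N_SECTORS)],
         "discounted": [costs.per_person_disc[:, i].sum() / n for i in range(N_SECTORS)]},
        index=list(SECTORS))

    # by fracture type: direct costs excluding LTC (NH episodes are not
    # split by triggering fracture; LTC appears only in the sector table)
    direct_idx = [_SEC[s] for s in DIRECT_SECTORS if s != "long_term_care"]
    by_type_costs = pd.DataFrame(
        {"undiscounted": costs.by_type[:, direct_idx].sum(axis=1) / n,
         "discounted": costs.by_type_disc[:, direct_idx].sum(axis=1) / n},
        index=[f.label for f in FractureType])

    total_direct = {
        "undiscounted": costs.total_direct(discounted=False),
        "discounted": costs.total_direct(discounted=True),
    }

    ages = result.start_age + np.arange(result.n_years)
    alive = result.alive_at_start.astype(float)
    annual = pd.DataFrame({
        "age": ages,
        "alive": result.alive_at_start,
        "direct_cost_per_capita": np.divide(costs.by_year_direct, alive,
                                            out=np.zeros_like(costs.by_year_direct),
                                            where=alive > 0),
    })

    return CohortSummary(
        label=result.scenario.label, n=n, mean_counts=mean_counts,
        count_distribution=count_distribution, sector_costs=sector_costs,
        by_type_costs=by_type_costs, total_direct=total_direct,
        annual_direct_per_capita=annual,
    )


@dataclass
class ExcessSummary:
    """Average-risk minus never-osteoporosis differences on CRN-paired cohorts."""

    mean_counts: dict[str, float]
    attribution_pct: dict[str, float]           # excess / average-risk x 100
    sector_costs: pd.DataFrame
    by_type_costs: pd.DataFrame
    total_direct: dict[str, float]
    annual_direct_per_capita: pd.DataFrame


def excess(average: CohortSummary, never: CohortSummary) -> ExcessSummary:
    counts = {k: average.mean_counts[k] - never.mean_counts[k] for k in average.mean_counts}
    attribution = {k: (100.0 * counts[k] / average.mean_counts[k]
                       if average.mean_counts[k] > 0 else float("nan"))
                   for k in counts}
    annual = average.annual_direct_per_capita.copy()
    annual["direct_cost_per_capita"] = (
        average.annual_direct_per_capita["direct_cost_per_capita"]
        - never.annual_direct_per_capita["direct_cost_per_capita"])
    annual["alive"] = average.annual_direct_per_capita["alive"]
    return ExcessSummary(
        mean_counts=counts,
        attribution_pct=attribution,
        sector_costs=average.sector_costs - never.sector_costs,
        by_type_costs=average.by_type_costs - never.by_type_costs,
        total_direct={k: average.total_direct[k] - never.total_direct[k]
                      for k in average.total_direct},
        annual_direct_per_capita=annual,
    )
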