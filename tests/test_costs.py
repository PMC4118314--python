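"""Cost attachment rules, LTC attribution, productivity, discounting."""

import numpy as np
import pytest

import osteosim as om
from osteosim.cohort import NEVER, CohortResult, EventTable
from osteosim.costs import (
    SECTORS,
    acute_fracture_costs,
    aggregate,
    compute_costs,
    discount,
    ltc_attribution_years,
)
from osteosim.parameters import FractureType


def make_cohort(n=1, start_age=50, **overrides) -> CohortResult:
    """Synthetic cohort result with explicit event structure (no simulation)."""
    T = 100 - start_age
    scenario = om.ScenarioSpec(start_age, "C", "avO", "avP")
    defaults = dict(
        scenario=scenario, n=n, seed=0,
        death_year=np.full(n, -1, dtype=np.int32),
        fracture_related_death=np.zeros(n, dtype=bool),
        osteo_start=np.zeros(n, dtype=bool),
        osteo_onset_year=np.full(n, -1, dtype=np.int32),
        prevfx_start=np.zeros(n, dtype=bool),
        nh_entry_year=np.full(n, NEVER, dtype=np.int32),
        nh_cause=np.zeros(n, dtype=np.int8),
        cf_entry_year=np.full(n, NEVER, dtype=np.int32),
        events=EventTable(person=np.zeros(0, np.int32), year=np.zeros(0, np.int32),
                          ftype=np.zeros(0, np.int8), hospitalized=np.zeros(0, bool),
                          rehab=np.zeros(0, bool)),
        counts=np.zeros((n, 6), dtype=np.uint16),
        alive_at_start=np.full(T, n, dtype=np.int64),
        fractures_by_year=np.zeros((T, 6), dtype=np.int64),
    )
    defaults.update(overrides)
    return CohortResult(**defaults)


def one_event(person=0, year=0, ftype=0, hospitalized=True, rehab=False) -> EventTable:
    return EventTable(person=np.array([person], np.int32), year=np.array([year], np.int32),
                      ftype=np.array([ftype], np.int8),
                      hospitalized=np.array([hospitalized]), rehab=np.array([rehab]))


class TestDiscount:
    def test_base_year_and_zero_rate_are_identity(self):
        assert discount(100.0, 2009, 0.03) == pytest.approx(100.0)
        assert discount(734.5, 2031, 0.0) == pytest.approx(734.5)

    def test_ten_year_ltc_example(self):
        assert discount(25_759, 2019, 0.03) == pytest.approx(19_167.1, abs=0.05)

    def test_flows_before_base_year_rejected(self):
        with pytest.raises(ValueError):
            discount(1.0, 2008, 0.03)


class TestAcuteFractureCosts:
    def test_hospitalized_hip_community_over_65(self, params):
        c = acute_fracture_costs(FractureType.HIP, True, True, 70, False, params)
        assert c["hospital"] == 8_554
        assert c["rehabilitation"] == 2_187
        assert c["professional_home_care"] == 2_174
        assert c["informal_care"] == 2_361
        assert c["outpatient"] == 0

    def test_outpatient_wrist_at_60_gets_no_home_care(self, params):
        c = acute_fracture_costs(FractureType.WRIST, False, False, 60, False, params)
        assert c["outpatient"] == 835
        assert c["hospital"] == c["professional_home_care"] == c["informal_care"] == 0

    def test_nh_resident_gets_hospital_pathway_only(self, params):
        c = acute_fracture_costs(FractureType.HIP, True, False, 80, True, params)
        assert c["hospital"] == 8_554
        assert c["professional_home_care"] == c["informal_care"] == 0


class TestLtcAttribution:
    def test_walkthrough(self, params):
        # fracture-NH entry year 5, counterfactual entry year 8, death year 10
        assert ltc_attribution_years(5, 8, 10) == 2.5
        res = make_cohort(
            nh_entry_year=np.array([5], np.int32), nh_cause=np.array([1], np.int8),
            cf_entry_year=np.array([8], np.int32), death_year=np.array([10], np.int32))
        c = compute_costs(res, params, discount_rate=0.0)
        ltc = c.per_person[0, SECTORS.index("long_term_care")]
        assert ltc == pytest.approx(2.5 * 25_759)  # == 64,397.5

    def test_background_entry_attracts_nothing(self, params):
        res = make_cohort(nh_entry_year=np.array([5], np.int32),
                          nh_cause=np.array([2], np.int8))
        c = compute_costs(res, params)
        assert c.per_person[0, SECTORS.index("long_term_care")] == 0.0

    def test_counterfactual_not_later_means_zero(self):
        assert ltc_attribution_years(5, 5, 20) == 0.0
        assert ltc_attribution_years(5, 3, 20) == 0.0

    def test_attribution_bounded_by_residence_years(self, params, small_cohort,
                                                    small_costs):
        ltc = small_costs.per_person[:, SECTORS.index("long_term_care")]
        years_in_nh = np.where(
            small_cohort.nh_entry_year < NEVER,
            small_cohort.last_alive_year() - np.maximum(small_cohort.nh_entry_year, 0) + 1,
            0)
        assert np.all(ltc <= years_in_nh * params.ltc_yearly_cost + 1e-9)


class TestProductivity:
    def _params(self, params, **kw):
        inp = params.inputs.copy()
        inp.employment_rate = np.ones(10)
        inp.wage_growth = 0.0
        for k, v in kw.items():
            setattr(inp, k, v)
        return om.build_parameter_set(inp)

    def test_death_at_60_half_cycle_stream(self, params):
        p = self._params(params)
        res = make_cohort(death_year=np.array([10], np.int32),
                          fracture_related_death=np.array([True]))
        c = compute_costs(res, p, discount_rate=0.0)
        hca = c.per_person[0, SECTORS.index("productivity_hca")]
        assert hca == pytest.approx(4.5 * p.yearly_earnings)
        fca = c.per_person[0, SECTORS.index("productivity_fca")]
        assert fca == pytest.approx(p.friction_period_years * p.yearly_earnings)

    def test_fractures_after_retirement_cost_nothing(self, params):
        p = self._params(params)
        res = make_cohort(events=one_event(year=20, ftype=0))  # age 70
        c = compute_costs(res, p)
        assert c.per_person[0, SECTORS.index("productivity_hca")] == 0.0
        assert c.per_person[0, SECTORS.index("productivity_fca")] == 0.0

    def test_morbidity_identical_under_both_approaches_below_friction(self, params):
        # 35 work days lost (wrist) < 62.5-day friction period
        p = self._params(params)
        res = make_cohort(events=one_event(year=5, ftype=int(FractureType.WRIST),
                                           hospitalized=False))
        c = compute_costs(res, p, discount_rate=0.0)
        hca = c.per_person[0, SECTORS.index("productivity_hca")]
        fca = c.per_person[0, SECTORS.index("productivity_fca")]
        assert hca == pytest.approx(fca)
        assert hca == pytest.approx(p.yearly_earnings / 250.0 * 35.0)


class TestConservationInvariants:
    def test_sector_and_type_totals_agree(self, small_cohort, small_costs):
        n = small_cohort.n
        summary = aggregate(small_cohort, small_costs)
        for col, disc in (("undiscounted", False), ("discounted", True)):
            total = summary.total_direct[col]
            by_sector = summary.sector_costs[col][:6].sum()
            assert by_sector == pytest.approx(total, rel=1e-9)
            ltc = summary.sector_costs[col]["long_term_care"]
            by_type = summary.by_type_costs[col].sum()
            assert by_type + ltc == pytest.approx(total, rel=1e-9)

    def test_discounted_never_exceeds_undiscounted(self, small_costs):
        assert np.all(small_costs.per_person_disc <= small_costs.per_person + 1e-9)

    def test_zero_unit_costs_zero_totals(self, params, small_cohort):
        inp = params.inputs.copy()
        for attr in ("hospital_cost", "rehab_cost", "outpatient_cost",
                     "home_care_cost", "informal_care_cost"):
            setattr(inp, attr, np.zeros(6))
        inp.ltc_yearly_cost = 0.0
        inp.yearly_earnings = 0.0
        p0 = om.build_parameter_set(inp)
        c = compute_costs(small_cohort, p0)
        assert c.per_person.sum() == 0.0 and c.per_person_disc.sum() == 0.0


class TestAggregate:
    def test_single_hip_event_per_capita(self, params):
        res = make_cohort(events=one_event(), counts=np.array([[1, 0, 0, 0, 0, 0]],
                                                              dtype=np.uint16))
        summary = aggregate(res, compute_costs(res, params))
        # event in 2009 at age 50: hospital cost only, no discounting yet
        assert summary.sector_costs.loc["hospital", "undiscounted"] == 8_554
        assert summary.sector_costs.loc["hospital", "discounted"] == 8_554
        assert summary.mean_counts["hip"] == 1.0

    def test_per_capita_averages_over_cohort(self, params):
        res = make_cohort(n=2, events=one_event(person=0))
        summary = aggregate(res, compute_costs(res, params))
        assert summary.sector_costs.loc["hospital", "undiscounted"] == 8_554 / 2

    def test_count_distribution_rows_sum_to_one(self, small_cohort, small_costs):
        summary = aggregate(small_cohort, small_costs)
        assert np.allclose(summary.count_distribution.sum(axis=1), 1.0)

    def test_empty_cohort_rejected(self, params, small_cohort, small_costs):
        import dataclasses
        empty = dataclasses.replace(small_cohort, n=0)
        with pytest.raises(ValueError):
            aggregate(empty, small_costs)
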