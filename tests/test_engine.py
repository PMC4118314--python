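"""Per-woman engine semantics, vector/scalar equivalence, CRN contract."""

import dataclasses

import numpy as np
import pytest

import osteosim as om
from osteosim.cohort import NEVER, run_cohort
from osteosim.engine import (
    BASE_CASE,
    ScenarioSpec,
    WomanState,
    draw_events,
    mortality_probability,
    nh_entry_decision,
    preload_state,
    simulate_individual,
    step_year,
)
from osteosim.fixtures import homogeneous_inputs, toy_world
from osteosim.parameters import FractureType, build_parameter_set


class TestScenarioSpec:
    def test_exactly_18_scenarios_and_no_nh_start_at_50(self):
        scenarios = om.enumerate_scenarios()
        assert len(scenarios) == 18
        assert all(not (s.start_age == 50 and s.residence == "N") for s in scenarios)
        labels = {s.label for s in scenarios}
        assert "50_C_avO_nP" in labels and "75_N_O_P" in labels

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(50, "N", "avO", "nP")
        with pytest.raises(ValueError):
            ScenarioSpec(60, "C", "avO", "nP")
        assert ScenarioSpec.from_label("75_N_nO_P").label == "75_N_nO_P"


class TestPreload:
    def test_forced_states(self, params):
        s = preload_state(ScenarioSpec(50, "C", "nO", "nP"), params, 0, 0)
        assert not s.osteoporotic and not s.prevalent_fracture
        assert not s.can_develop_osteoporosis
        s = preload_state(ScenarioSpec(50, "C", "O", "P"), params, 0, 0)
        assert s.osteoporotic and s.prevalent_fracture
        s = preload_state(ScenarioSpec(75, "N", "avO", "nP"), params, 0, 0)
        assert s.in_nh and s.residence_cause == "none"

    def test_degenerate_prevalence_forces_preload(self, params):
        forced = dataclasses.replace(params, osteo_prevalence=np.ones(51))
        assert all(preload_state(BASE_CASE, forced, 0, i).osteoporotic for i in range(20))


class TestDraws:
    def test_event_fires_iff_u_at_most_p(self):
        p = np.array([0.49, 0.50, 0.0, 1.0, 0.5, 0.5])
        u = np.array([0.50, 0.50, 0.0, 1.0, 0.9, 0.1])
        fired = draw_events(p, u)
        assert list(fired) == [False, True, True, True, False, True]

    def test_degenerate_probabilities(self):
        assert not draw_events(np.zeros(6), np.random.rand(6) + 1e-12).any()
        assert draw_events(np.ones(6), np.random.rand(6)).all()


class TestNursingHomeEntry:
    def test_under_entry_age_never_enters(self, params):
        state = WomanState(person_index=0, age=60)
        assert nh_entry_decision(state, [0], params, 0.0, 0.0) == "none"

    def test_resident_is_absorbed(self, params):
        state = WomanState(person_index=0, age=80, residence="nursing_home")
        assert nh_entry_decision(state, [0], params, 0.0, 0.0) == "none"

    def test_highest_admission_probability_governs(self, params):
        # hip admission at 80-84 is 0.18, wrist 0.027: a draw between the two
        # fires entry exactly when the hip fracture is in the acute set
        state = WomanState(person_index=0, age=82)
        u = 0.10
        hip, wrist = int(FractureType.HIP), int(FractureType.WRIST)
        assert nh_entry_decision(state, [wrist, hip], params, u, 0.99) == "fracture"
        assert nh_entry_decision(state, [wrist], params, u, 0.99) == "none"


class TestMortality:
    def _state(self, age, history):
        s = WomanState(person_index=0, age=age)
        s.year = 30
        s.fracture_history = [(f, 30 - back, True) for f, back in history]
        return s

    def test_no_history_community_baseline(self, homog_mortal_params):
        s = self._state(70, [])
        q = mortality_probability(s, homog_mortal_params)
        assert q == pytest.approx(float(homog_mortal_params.all_cause_q[20]))

    def test_max_rule_over_history(self, params):
        hip, hum = FractureType.HIP, FractureType.HUMERUS
        q_hip = mortality_probability(self._state(70, [(hip, 0)]), params)
        q_both = mortality_probability(self._state(70, [(hum, 0), (hip, 0)]), params)
        q_hum = mortality_probability(self._state(70, [(hum, 0)]), params)
        assert q_both == pytest.approx(q_hip)
        assert q_hum < q_hip

    def test_bucket_windows(self, params):
        hip = FractureType.HIP
        rr = params.rr_fracture_mortality[hip, 2]  # 70-79 age class
        base = mortality_probability(self._state(70, []), params)
        for back, expected_rr in [(0, rr[0]), (1, rr[1]), (4, rr[1]),
                                  (5, rr[2]), (9, rr[2]), (10, 1.0), (12, 1.0)]:
            q = mortality_probability(self._state(70, [(hip, back)]), params)
            assert q == pytest.approx(base * expected_rr), back

    def test_wrist_carries_no_excess(self, params):
        base = mortality_probability(self._state(70, []), params)
        q = mortality_probability(self._state(70, [(FractureType.WRIST, 0)]), params)
        assert q == pytest.approx(base)


class TestStepAndSimulate:
    def test_zero_world_runs_to_age_100(self):
        p, _ = toy_world("no_mortality_flat_hazard")
        inp = p.inputs.copy()
        inp.p_general = np.zeros_like(inp.p_general)
        p0 = build_parameter_set(inp)
        h = simulate_individual(BASE_CASE, p0, 0, 0)
        assert len(h.records) == 51
        assert h.records[-1].age == 100 and not h.records[-1].died
        assert h.fracture_count == 0 and h.death_year is None

    def test_certain_death_gives_one_record(self):
        p, expect = toy_world("certain_death_year1")
        h = simulate_individual(BASE_CASE, p, 0, 0)
        assert len(h.records) == expect["expected_history_length"]
        assert h.records[0].died

    def test_step_is_deterministic_given_seed(self, params):
        recs = []
        for _ in range(2):
            state = preload_state(BASE_CASE, params, 5, 3)
            recs.append(step_year(state, params, 5))
        assert recs[0] == recs[1]

    def test_dead_state_rejected(self, params):
        state = preload_state(BASE_CASE, params, 0, 0)
        state.alive = False
        with pytest.raises(ValueError):
            step_year(state, params, 0)


class TestAbsorptionInvariants:
    def test_no_reversals_no_posthumous_records(self, params):
        for i in range(40):
            h = simulate_individual(BASE_CASE, params, 13, i)
            was_osteo = h.osteo_preloaded
            in_nh = False
            for k, r in enumerate(h.records):
                assert r.age <= 100
                if r.osteoporosis_onset:
                    assert not was_osteo
                    was_osteo = True
                if r.nh_entry != "none":
                    assert not in_nh
                    in_nh = True
                if r.died:
                    assert k == len(h.records) - 1


class TestVectorScalarEquivalence:
    @pytest.mark.parametrize("label", ["50_C_avO_avP", "75_N_avO_nP", "50_C_O_P"])
    def test_cohort_matches_per_woman_engine(self, params, label):
        scenario = ScenarioSpec.from_label(label)
        n = 25
        res = run_cohort(scenario, params, n, seed=21)
        for i in range(n):
            h = simulate_individual(scenario, params, 21, i)
            dy = -1 if h.death_year is None else h.death_year
            assert dy == res.death_year[i]
            assert np.array_equal(h.fracture_counts_by_type(), res.counts[i])
            assert h.osteo_preloaded == res.osteo_start[i]
            assert h.prevfx_preloaded == res.prevfx_start[i]
            cf = next((r.year for r in h.records if r.background_nh_entry), NEVER)
            assert cf == res.cf_entry_year[i]


class TestCommonRandomNumbers:
    def test_same_seed_reproduces_byte_identical_results(self, params, small_cohort):
        res2 = run_cohort(BASE_CASE, params, small_cohort.n, seed=11)
        assert np.array_equal(res2.counts, small_cohort.counts)
        assert np.array_equal(res2.death_year, small_cohort.death_year)
        assert np.array_equal(res2.events.person, small_cohort.events.person)

    def test_identical_risk_groups_have_zero_excess(self, homog_params):
        """With all RRs forced to 1 the two risk groups are event-identical."""
        a = run_cohort(BASE_CASE, homog_params, 400, seed=3)
        b = run_cohort(om.BASE_CASE_NEVER, homog_params, 400, seed=3)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.death_year, b.death_year)
        assert np.array_equal(a.nh_entry_year, b.nh_entry_year)

    def test_draws_do_not_depend_on_cohort_size(self, params):
        big = run_cohort(BASE_CASE, params, 300, seed=9)
        small = run_cohort(BASE_CASE, params, 120, seed=9)
        assert np.array_equal(big.counts[:120], small.counts)
        assert np.array_equal(big.death_year[:120], small.death_year)

    def test_scaling_probabilities_up_never_loses_fractures(self):
        """Inverse-draw coupling: with feedback off, higher hazards dominate."""
        inp = homogeneous_inputs(no_mortality=True)
        lo = build_parameter_set(inp)
        hi_inp = inp.copy()
        hi_inp.p_general = np.clip(hi_inp.p_general * 1.5, 0, 1)
        hi = build_parameter_set(hi_inp)
        a = run_cohort(BASE_CASE, lo, 600, seed=17)
        b = run_cohort(BASE_CASE, hi, 600, seed=17)
        assert np.all(b.counts.astype(int) >= a.counts.astype(int))


class TestClosedFormLimit:
    def test_flat_hazard_expected_count(self):
        p, expect = toy_world("no_mortality_flat_hazard")
        res = run_cohort(BASE_CASE, p, 4_000, seed=29)
        mean_hip = res.counts[:, 0].mean()
        se = np.sqrt(50 * 0.01 * 0.99 / 4_000)
        assert abs(mean_hip - expect["expected_counts"]["hip"]) < 3 * se
        assert res.counts[:, 1:].sum() == 0
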