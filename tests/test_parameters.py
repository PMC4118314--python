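"""Derivation formulas, calibration identities, parameter I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import osteosim as om
from osteosim.parameters import (
    AGE_CLASS_LABELS,
    AgeClassSchedule,
    FractureType,
    ParameterError,
    age_class_index,
    build_parameter_set,
    derive_total_fracture_probability,
    fracture_prob_by_history,
    prevalence_to_incidence,
    rr_no_previous_fracture,
    rr_non_osteoporotic,
    rr_osteoporotic,
)


class TestDerivationFormulas:
    @pytest.mark.parametrize("rate,hp,expected", [
        (0.00038, 1.0, 0.00038),   # femoral fractures: all hospitalized
        (0.0, 0.5, 0.0),
        (0.003, 0.6, 0.005),
    ])
    def test_hospital_case_inflation(self, rate, hp, expected):
        assert derive_total_fracture_probability(rate, hp) == pytest.approx(expected)

    def test_hospital_case_inflation_clips_and_rejects_zero(self):
        assert derive_total_fracture_probability(0.9, 0.5) == 1.0
        with pytest.raises(ParameterError):
            derive_total_fracture_probability(0.1, 0.0)

    @pytest.mark.parametrize("rr,prev,expected", [
        (3.7, 0.0, 1.0),    # nobody has a previous fracture
        (1.0, 0.4, 1.0),    # no risk elevation
        (2.0, 0.25, 0.8),
    ])
    def test_no_previous_fracture_rr(self, rr, prev, expected):
        assert rr_no_previous_fracture(rr, prev) == pytest.approx(expected)

    @pytest.mark.parametrize("p,rnp,rp,has,expected", [
        (0.01, 1.0, 1.0, True, 0.01),
        (0.01, 0.8, 2.0, True, 0.016),
        (0.01, 0.8, 2.0, False, 0.008),
    ])
    def test_history_adjustment(self, p, rnp, rp, has, expected):
        assert fracture_prob_by_history(p, rnp, rp, has) == pytest.approx(expected)

    @pytest.mark.parametrize("rr,prev,expected", [
        (1.0, 0.3, 1.0),
        (2.5, 0.0, 1.0),
        (4.0, 0.2, 0.25),
    ])
    def test_non_osteoporotic_rr(self, rr, prev, expected):
        assert rr_non_osteoporotic(rr, prev) == pytest.approx(expected)

    def test_non_osteoporotic_rr_rejects_inconsistency(self):
        with pytest.raises(ParameterError):
            rr_non_osteoporotic(4.0, 0.3)

    @pytest.mark.parametrize("lo,hi,span,expected", [
        (0.1, 0.1, 5, 0.0),
        (0.0, 0.2, 5, 1 - 0.8 ** 0.2),       # ~0.04365
        (0.0, 0.04, 5, 1 - 0.96 ** 0.2),     # ~0.008131
    ])
    def test_prevalence_to_incidence(self, lo, hi, span, expected):
        assert prevalence_to_incidence(lo, hi, span) == pytest.approx(expected, rel=1e-12)

    def test_prevalence_to_incidence_irreversibility(self):
        with pytest.raises(ParameterError):
            prevalence_to_incidence(0.3, 0.2, 5)
        assert prevalence_to_incidence(0.3, 0.2, 5, floor_at_zero=True) == 0.0

    def test_prevalence_to_incidence_round_trip(self):
        """Applying the derived q reproduces the prevalence ladder exactly."""
        ladder = np.array([0.05, 0.11, 0.18, 0.31, 0.44])
        prev = ladder[0]
        for lo, hi in zip(ladder[:-1], ladder[1:]):
            q = prevalence_to_incidence(lo, hi, 5)
            for _ in range(5):
                prev = prev + (1 - prev) * q
            assert prev == pytest.approx(hi, abs=1e-12)


def _rr_ost_oracle(gradient, mean, threshold):
    """Brute-force numerical integration of the osteoporotic relative risk."""
    risk = lambda z: gradient ** (-(z + mean))  # T = z + mean, z ~ N(0,1)
    num = quad(lambda z: risk(z) * norm.pdf(z), -12, threshold - mean)[0]
    den = quad(lambda z: risk(z) * norm.pdf(z), -12, 12)[0]
    prob = norm.cdf(threshold - mean)
    return (num / prob) / den


class TestOsteoporoticRelativeRisk:
    def test_unit_gradient_is_neutral(self):
        assert rr_osteoporotic(1.0, -0.7) == pytest.approx(1.0)

    def test_all_inclusive_threshold_is_neutral(self):
        # "osteoporosis" includes essentially everyone
        assert rr_osteoporotic(2.0, 0.0, threshold=8.0) == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_matches_integration_oracle(self):
        for g in (1.0, 1.3, 2.0, 2.9, 4.0):
            for m in (-2.0, -1.2, -0.4, 0.5, 1.0):
                closed = rr_osteoporotic(g, m, -2.5)
                oracle = _rr_ost_oracle(g, m, -2.5)
                assert closed == pytest.approx(oracle, rel=1e-6), (g, m)

    def test_monotone_in_gradient_and_mean(self):
        # steeper gradient -> higher subgroup risk; a healthier population
        # (higher mean T-score) makes the osteoporotic tail more selected and
        # therefore *raises* its relative risk
        grid_g = np.linspace(1.0, 4.0, 13)
        grid_m = np.linspace(-2.0, 1.0, 13)
        for m in grid_m:
            vals = [rr_osteoporotic(g, m, -2.5) for g in grid_g]
            assert np.all(np.diff(vals) >= -1e-12)
        for g in grid_g[1:]:
            vals = [rr_osteoporotic(g, m, -2.5) for m in grid_m]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_underflow_raises(self):
        with pytest.raises(ParameterError):
            rr_osteoporotic(2.0, 40.0, -2.5)


class TestCalibrationIdentities:
    def test_default_set_identities_exact(self, params):
        """Prevalence-weighted subgroup RRs equal 1 at every age, both splits."""
        w_ost = params.osteo_prevalence * params.rr_ost \
            + (1 - params.osteo_prevalence) * params.rr_noost
        assert np.max(np.abs(w_ost - 1)) < 1e-12

        pf = params.prevfx_prevalence
        rr_any = params.inputs.rr_any_prev
        w_pf = pf * rr_any * params.rr_noprev + (1 - pf) * params.rr_noprev
        assert np.max(np.abs(w_pf - 1)) < 1e-12

        s = params.nh_share
        w_res = s * params.rr_res_nh[:, None] + (1 - s) * params.rr_res_comm
        assert np.max(np.abs(w_res - 1)) < 1e-12
        w_mort = s * params.rr_mortality_nh + (1 - s) * params.rr_mortality_comm
        assert np.max(np.abs(w_mort - 1)) < 1e-12

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_random_valid_sets_keep_identities(self, seed):
        p = build_parameter_set(om.random_valid_parameters(seed))
        w_ost = p.osteo_prevalence * p.rr_ost + (1 - p.osteo_prevalence) * p.rr_noost
        assert np.max(np.abs(w_ost - 1)) < 1e-12
        w_pf = p.prevfx_prevalence * p.inputs.rr_any_prev * p.rr_noprev \
            + (1 - p.prevfx_prevalence) * p.rr_noprev
        assert np.max(np.abs(w_pf - 1)) < 1e-12

    def test_derived_probabilities_in_range(self, params):
        assert np.all(params.osteo_incidence >= 0) and np.all(params.osteo_incidence <= 1)
        assert np.all(params.bg_nh_incidence >= 0) and np.all(params.bg_nh_incidence <= 1)
        assert np.all(params.prevfx_prevalence >= 0) and np.all(params.prevfx_prevalence < 1)
        for f in range(6):
            for age in range(50, 101):
                for ost in (True, False):
                    p = params.fracture_probability(f, age, ost, True, False)
                    assert 0.0 <= float(p) <= 1.0


class TestValidationAndTypes:
    def test_age_class_lookup(self):
        assert age_class_index(50) == 0
        assert age_class_index(54) == 0
        assert age_class_index(55) == 1
        assert age_class_index(94) == 8
        assert [age_class_index(a) for a in (95, 100)] == [9, 9]
        with pytest.raises(ValueError):
            age_class_index(49)

    def test_schedule_requires_ten_finite_bands(self):
        sched = AgeClassSchedule(tuple(range(10)))
        assert sched.at_age(72) == 4
        with pytest.raises(ValueError):
            AgeClassSchedule((1.0,) * 9)

    def test_out_of_range_probability_rejected_with_collected_issues(self):
        bad = om.default_inputs()
        bad.p_general = bad.p_general.copy()
        bad.p_general[0, 0] = 1.2
        bad.rehab_prob = bad.rehab_prob.copy()
        bad.rehab_prob[2] = -0.1
        with pytest.raises(ParameterError) as exc:
            build_parameter_set(bad)
        assert len(exc.value.issues) >= 2

    def test_femoral_hospitalization_must_be_certain(self):
        bad = om.default_inputs()
        bad.hospitalization_prob = bad.hospitalization_prob.copy()
        bad.hospitalization_prob[0] = 0.9
        with pytest.raises(ParameterError):
            build_parameter_set(bad)

    def test_forced_unit_rrs_make_risk_groups_identical(self, homog_params):
        p = homog_params
        for age in (50, 67, 83, 99):
            for f in range(6):
                base = p.fracture_probability(f, age, False, False, False)
                assert p.fracture_probability(f, age, True, True, True) \
                    == pytest.approx(float(base))


class TestCsvRoundTrip:
    def test_write_load_rebuild(self, tmp_path, params):
        om.write_parameter_tables(params.inputs, tmp_path)
        reloaded = om.load_parameter_tables(tmp_path)
        p2 = build_parameter_set(reloaded)
        assert np.allclose(p2.p_general, params.p_general, rtol=0, atol=0)
        assert np.allclose(p2.rr_ost, params.rr_ost)
        assert np.allclose(p2.all_cause_q, params.all_cause_q)
        assert np.allclose(p2.hospital_cost, params.hospital_cost)
        assert p2.inputs.rr_any_prev_ci == params.inputs.rr_any_prev_ci
        assert reloaded.placeholders() == params.inputs.placeholders()

    def test_strict_header_validation(self, tmp_path):
        (tmp_path / "bad.csv").write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ParameterError):
            om.load_parameter_tables(tmp_path)
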