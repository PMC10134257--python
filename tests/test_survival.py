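"""Probability/rate conversions, transition derivation, calibration and HRs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nsclc_cea as n
from nsclc_cea.errors import CalibrationError
from nsclc_cea.survival import (apply_hazard_ratio, boundary_survival,
                                build_arm_schedule, calibrate_pd_death,
                                calibrate_reference, extrapolate_schedule,
                                pfs_to_transitions, prob_to_rate, rate_to_prob,
                                read_transition_schedule,
                                write_transition_schedule)
from nsclc_cea.synthetic import (PiecewiseExpSpec, make_cohort_curves,
                                 transition_schedule_from_hazards)


class TestConversions:
    @pytest.mark.parametrize("p,r", [(0.0, 0.0), (0.5, np.log(2)),
                                     (0.632121, 1.0)])
    def test_prob_to_rate(self, p, r):
        assert prob_to_rate(p) == pytest.approx(r, abs=1e-5)

    @pytest.mark.parametrize("r,p", [(0.0, 0.0), (np.log(2), 0.5)])
    def test_rate_to_prob(self, r, p):
        assert rate_to_prob(r) == pytest.approx(p, abs=1e-12)

    def test_roundtrip_on_grid(self):
        p = np.arange(0.0, 1.0, 0.01)
        np.testing.assert_allclose(rate_to_prob(prob_to_rate(p)), p, atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            prob_to_rate(1.0)
        with pytest.raises(ValueError):
            rate_to_prob(-0.1)
        with pytest.raises(ValueError):
            apply_hazard_ratio(0.1, 0.0)

    @pytest.mark.parametrize("p,hr,expected", [
        (0.1, 1.0, 0.1),
        (0.5, 2.0, 0.75),
        (0.1, 0.5, 0.051317),  # 1 - 0.9**0.5
    ])
    def test_apply_hazard_ratio(self, p, hr, expected):
        assert apply_hazard_ratio(p, hr) == pytest.approx(expected, abs=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(p=st.floats(0.0, 0.99), hr=st.floats(0.01, 5.0))
    def test_hr_is_rate_scale_composition(self, p, hr):
        assert apply_hazard_ratio(p, hr) == pytest.approx(
            rate_to_prob(hr * prob_to_rate(p)), abs=1e-12)


class TestPfsToTransitions:
    def curve(self, survival, dt=6.0):
        survival = np.asarray(survival, dtype=float)
        return n.SurvivalCurve("PFS", np.arange(len(survival)) * dt, survival)

    @pytest.mark.parametrize("surv,expected", [
        ((1, 0.9, 0.81), (0.1, 0.1)),        # constant hazard, geometric
        ((1, 1, 1), (0, 0)),                 # no progression
        ((1, 0.8, 0.7), (0.2, 0.125)),       # direct formula
        ((1, 0.5, 0.0, 0.0), (0.5, 1.0, 0.0)),  # exhausted curve: p=0 after S=0
    ])
    def test_examples(self, surv, expected):
        np.testing.assert_allclose(pfs_to_transitions(self.curve(surv), 6.0),
                                   expected, atol=1e-12)

    def test_short_followup_rejected(self):
        with pytest.raises(CalibrationError):
            pfs_to_transitions(self.curve((1, 0.9)), 6.0)

    def test_step_interpolation_between_digitized_points(self):
        # points at weeks 0, 4, 9: boundary at week 6 reads the week-4 value
        c = n.SurvivalCurve("PFS", [0.0, 4.0, 9.0, 14.0], [1.0, 0.9, 0.8, 0.7])
        np.testing.assert_allclose(boundary_survival(c, 6.0), [1.0, 0.9, 0.8])


class TestCalibration:
    def test_degenerate_no_deaths(self):
        # constant OS = PFS: no progression, PD occupancy stays 0, all q by
        # the carry rule are 0 and the modeled OS trivially matches
        pfs = n.SurvivalCurve("PFS", [0, 6, 12], [1, 1, 1])
        os_c = n.SurvivalCurve("OS", [0, 6, 12], [1, 1, 1])
        q, clips = calibrate_pd_death(os_c, pfs, pfs_to_transitions(pfs, 6.0), 6.0)
        np.testing.assert_array_equal(q, 0.0)
        assert clips == 0

    def test_carry_rule_while_pd_empty(self):
        # deaths demanded at cycle 0 cannot be produced (PD starts empty):
        # q0 falls back to the carried value 0
        pfs = n.SurvivalCurve("PFS", [0, 6, 12], [1, 0.9, 0.81])
        os_c = n.SurvivalCurve("OS", [0, 6, 12], [1, 0.95, 0.9025])
        q, _ = calibrate_pd_death(os_c, pfs, pfs_to_transitions(pfs, 6.0), 6.0)
        assert q[0] == 0.0
        # cycle 1 targets cumulative deaths 1-0.9025 from modeled PD = 0.1
        assert q[1] == pytest.approx(0.0975 / 0.1)

    def test_roundtrip_recovers_known_schedule(self):
        # simulate truth, extract curves, recalibrate: q recovered exactly
        rng = np.random.default_rng(42)
        p = rng.uniform(0.02, 0.3, 30)
        q_true = rng.uniform(0.02, 0.4, 30)
        ts = n.TransitionSchedule(p_pf_pd=p, p_pd_death=q_true, observed_cycles=30)
        trace = n.run_cohort(ts)
        t = np.arange(31) * 6.0
        pfs = n.SurvivalCurve("PFS", t, trace.pf)
        os_c = n.SurvivalCurve("OS", t, trace.pf + trace.pd)
        q_rec, clips = calibrate_pd_death(os_c, pfs, pfs_to_transitions(pfs, 6.0), 6.0)
        assert clips == 0
        pd_occ = trace.pd[:-1]
        mask = pd_occ > 1e-6
        np.testing.assert_allclose(q_rec[mask], q_true[mask], atol=1e-9)

    def test_fidelity_on_cohort_consistent_curves(self):
        pfs_spec = PiecewiseExpSpec(hazards=[0.03, 0.015], breakpoints=[24],
                                    follow_up=150)
        death_spec = PiecewiseExpSpec(hazards=[0.02], follow_up=150)
        pfs, os_c = make_cohort_curves(pfs_spec, death_spec)
        ts = calibrate_reference(pfs, os_c)
        trace = n.run_cohort(ts)
        nobs = ts.observed_cycles
        np.testing.assert_allclose(trace.pf[:nobs + 1],
                                   boundary_survival(pfs, 6.0), atol=1e-10)
        np.testing.assert_allclose((trace.pf + trace.pd)[:nobs + 1],
                                   boundary_survival(os_c, 6.0), atol=1e-10)

    def test_os_below_pfs_repaired_with_warning(self, caplog):
        pfs = n.SurvivalCurve("PFS", [0, 6, 12], [1, 0.9, 0.81])
        os_c = n.SurvivalCurve("OS", [0, 6, 12], [1, 0.85, 0.81])
        with caplog.at_level("WARNING"):
            calibrate_pd_death(os_c, pfs, pfs_to_transitions(pfs, 6.0), 6.0)
        assert any("repaired" in r.message for r in caplog.records)

    def test_excessive_clipping_fails_calibration(self):
        # OS that collapses far faster than PD can supply deaths forces clips
        t = np.arange(11) * 6.0
        pfs = n.SurvivalCurve("PFS", t, 0.995 ** np.arange(11))
        os_c = n.SurvivalCurve("OS", t, np.maximum(0.3 ** np.arange(11),
                                                   0.995 ** np.arange(11) * 0.999))
        with pytest.raises(CalibrationError, match="clipped"):
            calibrate_reference(pfs, os_c)


class TestExtrapolation:
    def test_constant_schedule_extends_flat(self, constant_schedule):
        ts = extrapolate_schedule(constant_schedule(p=0.1, q=0.2, cycles=10), 100)
        assert len(ts) == 100
        np.testing.assert_allclose(ts.p_pf_pd, 0.1)
        np.testing.assert_allclose(ts.p_pd_death, 0.2)

    def test_tail_window_mean(self):
        p = np.concatenate([np.full(7, 0.05), [0.2, 0.1, 0.3]])
        ts = n.TransitionSchedule(p_pf_pd=p, p_pd_death=p, observed_cycles=10)
        out = extrapolate_schedule(ts, 20, tail_window=3)
        np.testing.assert_allclose(out.p_pf_pd[10:], 0.2)  # mean of (0.2,0.1,0.3)
        out1 = extrapolate_schedule(ts, 20, tail_window=1)
        np.testing.assert_allclose(out1.p_pf_pd[10:], 0.3)

    def test_short_horizon_truncates(self, constant_schedule):
        out = extrapolate_schedule(constant_schedule(cycles=10), 4)
        assert len(out) == 4 and out.observed_cycles == 4

    def test_schedule_file_roundtrip(self, tmp_path, constant_schedule):
        ts = extrapolate_schedule(constant_schedule(cycles=10), 15)
        write_transition_schedule(ts, tmp_path / "s.csv")
        again = read_transition_schedule(tmp_path / "s.csv")
        np.testing.assert_array_equal(again.p_pf_pd, ts.p_pf_pd)
        assert again.observed_cycles == 10


class TestArmConstruction:
    def test_hr_one_is_identity(self, ref_all):
        arm = build_arm_schedule(ref_all, 1.0, 1.0)
        np.testing.assert_allclose(arm.p_pf_pd, ref_all.p_pf_pd, atol=1e-15)
        np.testing.assert_allclose(arm.p_pd_death, ref_all.p_pd_death, atol=1e-15)

    def test_closed_form_on_constant_schedule(self, constant_schedule):
        arm = build_arm_schedule(constant_schedule(p=0.1, q=0.1), 0.5, 1.0)
        np.testing.assert_allclose(arm.p_pf_pd, 1 - 0.9 ** 0.5, atol=1e-12)

    @pytest.mark.parametrize("hr", [0.3, 0.7, 1.0, 1.4])
    def test_lower_hr_means_higher_survival_everywhere(self, ref_all, hr):
        arm = build_arm_schedule(ref_all, hr, hr)
        ref_trace = n.run_cohort(ref_all)
        arm_trace = n.run_cohort(arm, horizon_cycles=ref_trace.cycles)
        alive_ref = ref_trace.pf + ref_trace.pd
        alive_arm = arm_trace.pf + arm_trace.pd
        if hr < 1:
            assert np.all(arm_trace.pf >= ref_trace.pf - 1e-15)
            assert np.all(alive_arm >= alive_ref - 1e-15)
        elif hr == 1.0:
            np.testing.assert_allclose(alive_arm, alive_ref, atol=1e-15)
        else:
            assert np.all(arm_trace.pf <= ref_trace.pf + 1e-15)

    def test_hr_must_be_positive(self, ref_all):
        with pytest.raises(ValueError):
            build_arm_schedule(ref_all, -1.0, 1.0)

    def test_arm_pfs_matches_powered_recursion(self, ref_all):
        # modeled arm PFS equals the reference PFS transformed cycle-wise
        hr = 0.6
        arm = build_arm_schedule(ref_all, hr, 1.0)
        trace = n.run_cohort(arm)
        expected = np.cumprod(np.concatenate([[1.0], (1 - ref_all.p_pf_pd) ** hr]))
        np.testing.assert_allclose(trace.pf, expected[:trace.cycles + 1], atol=1e-12)
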