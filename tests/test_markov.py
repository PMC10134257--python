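"""Cohort recursion, microsimulation oracle, discounting and accrual."""

import numpy as np
import pytest

import nsclc_cea as n
from nsclc_cea.errors import StrategyUnavailableError
from nsclc_cea.markov import (CohortTrace, accrue_costs, accrue_qalys,
                              discount_factor, evaluate_strategy,
                              microsim_oracle, run_cohort,
                              secondline_lump_cost)
from nsclc_cea.params import EconomicParams, StrategyDefinition


def schedule(p, q, cycles):
    return n.TransitionSchedule(p_pf_pd=np.full(cycles, float(p)),
                                p_pd_death=np.full(cycles, float(q)),
                                observed_cycles=cycles)


ECON_PLAIN = EconomicParams(annual_discount=0.0,
                            secondline_unit_costs={"chemo": 0, "immunotherapy": 0,
                                                   "targeted": 0})


class TestRunCohort:
    def test_immortal_cohort_stays_pf(self):
        tr = run_cohort(schedule(0, 0, 20))
        np.testing.assert_array_equal(tr.pf, 1.0)
        tr.validate()

    def test_instant_progression_then_death(self):
        tr = run_cohort(schedule(1, 1, 3))
        assert tr.pd[1] == 1.0 and tr.pf[1] == 0.0
        assert tr.dead[2] == 1.0
        tr.validate()

    def test_pd_closed_form_when_no_death(self):
        tr = run_cohort(schedule(0.1, 0.0, 50))
        t = np.arange(51)
        np.testing.assert_allclose(tr.pd, 1 - 0.9 ** t, atol=1e-12)
        tr.validate()

    def test_early_stop_on_alive_fraction(self):
        tr = run_cohort(schedule(0.5, 0.5, 200), stop_alive_fraction=1e-4)
        assert tr.cycles < 200
        assert tr.pf[-1] + tr.pd[-1] < 1e-4

    def test_mass_conserved_on_random_schedules(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ts = n.TransitionSchedule(p_pf_pd=rng.uniform(0, 1, 30),
                                      p_pd_death=rng.uniform(0, 1, 30),
                                      observed_cycles=30)
            run_cohort(ts).validate()


class TestMicrosim:
    def test_matches_cohort_within_mc_error(self):
        ts = schedule(0.1, 0.2, 30)
        cohort = run_cohort(ts)
        sim = microsim_oracle(ts, n_patients=100_000, seed=11)
        tol = 3 * np.sqrt(0.25 / 100_000)
        for attr in ("pf", "pd", "dead"):
            np.testing.assert_allclose(getattr(sim, attr), getattr(cohort, attr),
                                       atol=tol)

    def test_deterministic_under_seed(self):
        ts = schedule(0.2, 0.3, 10)
        a = microsim_oracle(ts, 1000, seed=5)
        b = microsim_oracle(ts, 1000, seed=5)
        np.testing.assert_array_equal(a.pf, b.pf)
        np.testing.assert_array_equal(a.dead, b.dead)

    def test_degenerate_schedule_exact(self):
        ts = schedule(0, 0, 10)
        sim = microsim_oracle(ts, 100, seed=0)
        np.testing.assert_array_equal(sim.pf, 1.0)


class TestDiscounting:
    @pytest.mark.parametrize("cycle,rate,expected", [
        (0, 0.03, 1.0),
        (52 / 6, 0.03, 1 / 1.03),        # exactly one elapsed year
        (1, 0.03, 1.03 ** (-6 / 52)),    # one 6-week cycle
        (10, 0.0, 1.0),
    ])
    def test_values(self, cycle, rate, expected):
        assert discount_factor(cycle, rate, 6.0) == pytest.approx(expected, abs=1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01, 6.0)


def geometric_trace(survival_per_cycle=0.9, cycles=400):
    """All-PF trace with alive fraction 0.9^t (closed-form test input)."""
    t = np.arange(cycles + 1)
    pf = survival_per_cycle ** t
    return CohortTrace(pf=pf, pd=np.zeros(cycles + 1), dead=1 - pf,
                       new_pd=np.zeros(cycles + 1))


class TestAccrueQalys:
    def test_geometric_life_expectancy_no_correction(self):
        # sum of 0.9^t = 10 cycles = 1.15385 years
        tr = geometric_trace()
        ly, q = accrue_qalys(tr, 1.0, 1.0, ECON_PLAIN, discounted=False,
                             half_cycle=False)
        assert ly == pytest.approx(10 * 6 / 52, abs=1e-9)
        assert q == pytest.approx(ly)

    def test_half_cycle_correction_shifts_half_cycle(self):
        # trapezoid: 10 - 0.5 = 9.5 cycles = 1.09615 years
        tr = geometric_trace()
        ly, _ = accrue_qalys(tr, 1.0, 1.0, ECON_PLAIN, discounted=False,
                             half_cycle=True)
        assert ly == pytest.approx(9.5 * 6 / 52, abs=1e-9)

    def test_zero_utilities_zero_qalys(self):
        tr = geometric_trace()
        ly, q = accrue_qalys(tr, 0.0, 0.0, ECON_PLAIN, discounted=False)
        assert q == 0.0 and ly > 0

    def test_qalys_bounded_by_life_years(self, study, ref_all):
        for sd in study.strategies_in("all"):
            o = evaluate_strategy(sd, ref_all, "all", study.econ)
            assert 0 <= o.qalys <= o.life_years
            assert o.qalys <= o.qalys_undiscounted
            assert o.life_years <= o.life_years_undiscounted


class TestAccrueCosts:
    def test_zero_cost_strategy(self):
        sd = StrategyDefinition(name="free")
        econ = EconomicParams(admin_cost_per_cycle=0, bsc_cost_per_cycle=0,
                              annual_discount=0.0,
                              secondline_unit_costs={"chemo": 0,
                                                     "immunotherapy": 0,
                                                     "targeted": 0})
        assert accrue_costs(run_cohort(schedule(0.1, 0.2, 50)), sd, econ) == 0.0

    def test_admin_only_immortal_cohort(self):
        sd = StrategyDefinition(name="admin_only")
        econ = EconomicParams(admin_cost_per_cycle=678, bsc_cost_per_cycle=0,
                              annual_discount=0.0,
                              secondline_unit_costs={"chemo": 0,
                                                     "immunotherapy": 0,
                                                     "targeted": 0})
        tr = run_cohort(schedule(0, 0, 2))
        assert accrue_costs(tr, sd, econ, half_cycle=False) == pytest.approx(1356)

    def test_io_cap_stops_drug_cost(self):
        econ = EconomicParams(admin_cost_per_cycle=0, bsc_cost_per_cycle=0,
                              annual_discount=0.0,
                              secondline_unit_costs={"chemo": 0,
                                                     "immunotherapy": 0,
                                                     "targeted": 0})
        sd = StrategyDefinition(name="io", io_max_cycles=17)
        sd.io_cost_per_cycle = 1000.0
        tr = run_cohort(schedule(0, 0, 40))
        cost = accrue_costs(tr, sd, econ, half_cycle=False)
        assert cost == pytest.approx(17 * 1000)  # cycles 17..39 accrue nothing

    def test_secondline_lump_is_mix_weighted(self):
        econ = EconomicParams(admin_cost_per_cycle=100,
                              secondline_duration_cycles=4,
                              secondline_unit_costs={"chemo": 134,
                                                     "immunotherapy": 23090,
                                                     "targeted": 13147})
        sd = StrategyDefinition(name="x", secondline_mix={
            "chemo": 0.5, "immunotherapy": 0.25, "targeted": 0.1})
        # IV classes include the per-cycle administration cost; oral does not
        expected = 0.5 * 4 * (134 + 100) + 0.25 * 4 * (23090 + 100) + 0.1 * 4 * 13147
        assert secondline_lump_cost(sd, econ) == pytest.approx(expected)

    def test_bsc_accrues_only_in_pd_by_default(self):
        econ = EconomicParams(admin_cost_per_cycle=0, bsc_cost_per_cycle=1000,
                              annual_discount=0.0,
                              secondline_unit_costs={"chemo": 0,
                                                     "immunotherapy": 0,
                                                     "targeted": 0})
        sd = StrategyDefinition(name="x")
        tr = run_cohort(schedule(0, 0, 10))  # immortal, never in PD
        assert accrue_costs(tr, sd, econ) == 0.0
        econ.bsc_in_pf = True
        assert accrue_costs(tr, sd, econ, half_cycle=False,
                            discounted=False) == pytest.approx(10_000)


class TestEvaluateStrategy:
    def test_reference_equals_direct_reference_evaluation(self, study, ref_all):
        chemo = study.strategies["chemotherapy"]
        o = evaluate_strategy(chemo, ref_all, "all", study.econ)
        tr = n.run_cohort(ref_all, study.econ.horizon_cycles(),
                          study.econ.stop_alive_fraction)
        ly, q = accrue_qalys(tr, chemo.utility_pf, study.econ.utility_pd, study.econ)
        assert o.life_years == pytest.approx(ly) and o.qalys == pytest.approx(q)

    def test_unavailable_stratum_raises(self, study, ref_all):
        with pytest.raises(StrategyUnavailableError):
            evaluate_strategy(study.strategies["pembrolizumab"], ref_all, "all",
                              study.econ)

    def test_discounting_reduces_every_total(self, study, ref_all):
        for sd in study.strategies_in("all"):
            o = evaluate_strategy(sd, ref_all, "all", study.econ)
            assert o.cost <= o.cost_undiscounted
            assert o.qalys <= o.qalys_undiscounted

    def test_utility_only_difference_preserves_life_years(self, study, ref_all):
        a = study.strategies["pembro_chemo"]
        b_ps = n.set_parameter(study, "strategy.pembro_chemo.utility_pf", 0.70)
        b = b_ps.strategies["pembro_chemo"]
        oa = evaluate_strategy(a, ref_all, "all", study.econ)
        ob = evaluate_strategy(b, ref_all, "all", b_ps.econ)
        assert oa.life_years == pytest.approx(ob.life_years, rel=1e-12)
        assert oa.qalys > ob.qalys
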