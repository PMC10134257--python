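"""Three-state cohort model and discounted cost/QALY accrual.

States: progression-free (PF) -> progressive disease (PD) -> dead.  The
cohort enters in PF; death occurs only from PD (no background mortality).
Per cycle ``t``::

    pf[t+1]   = pf[t] * (1 - p_t)
    new_pd    = pf[t] * p_t
    pd[t+1]   = pd[t] * (1 - q_t) + new_pd
    dead[t+1] = dead[t] + pd[t] * q_t

State-occupancy quantities (life years, QALYs, per-cycle drug/admin/BSC
costs) are half-cycle corrected by trapezoidal averaging of adjacent
boundary occupancies and discounted at an annual rate applied per cycle of
accrual.  One-time costs (adverse-event lump at entry, expected second-line
lump at PD entry) are discounted but not half-cycle corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StrategyUnavailableError
from .params import EconomicParams, StrategyDefinition, as_stratum
from .survival import TransitionSchedule, build_arm_schedule


@dataclass
class CohortTrace:
    """State occupancy per cycle boundary; arrays have length cycles + 1."""

    pf: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    new_pd: np.ndarray  # proportion entering PD during the preceding cycle

    @property
    def cycles(self) -> int:
        return len(self.pf) - 1

    @property
    def alive(self) -> np.ndarray:
        return self.pf + self.pd

    def validate(self, atol: float = 1e-12) -> None:
        total = self.pf + self.pd + self.dead
        assert np.allclose(total, 1.0, atol=atol), "occupancy rows must sum to 1"
        assert np.all(np.diff(self.dead) >= -atol), "dead occupancy must be non-decreasing"
        assert np.all(np.diff(self.pf) <= atol), "PF occupancy must be non-increasing"


@dataclass
class StrategyOutcome:
    """Discounted and undiscounted lifetime totals for one strategy."""

    strategy: str
    cost: float
    life_years: float
    qalys: float
    cost_undiscounted: float = 0.0
    life_years_undiscounted: float = 0.0
    qalys_undiscounted: float = 0.0


def run_cohort(ts: TransitionSchedule, horizon_cycles: int | None = None,
               stop_alive_fraction: float = 0.0) -> CohortTrace:
    """Run the cohort recursion; stops early once the alive fraction falls
    below ``stop_alive_fraction``."""
    n = len(ts) if horizon_cycles is None else min(horizon_cycles, len(ts))
    p, q = ts.p_pf_pd, ts.p_pd_death
    pf = np.empty(n + 1)
    pd_ = np.empty(n + 1)
    dead = np.empty(n + 1)
    new_pd = np.zeros(n + 1)
    pf[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
    t_end = n
    for t in range(n):
        inflow = pf[t] * p[t]
        new_pd[t + 1] = inflow
        pf[t + 1] = pf[t] - inflow
        dead[t + 1] = dead[t] + pd_[t] * q[t]
        pd_[t + 1] = pd_[t] * (1.0 - q[t]) + inflow
        if pf[t + 1] + pd_[t + 1] < stop_alive_fraction:
            t_end = t + 1
            break
    sl = slice(0, t_end + 1)
    return CohortTrace(pf=pf[sl], pd=pd_[sl], dead=dead[sl], new_pd=new_pd[sl])


def microsim_oracle(ts: TransitionSchedule, n_patients: int, seed: int,
                    horizon_cycles: int | None = None) -> CohortTrace:
    """Individual-level Monte-Carlo estimate of the cohort trace.

    Simulates ``n_patients`` independent paths with per-cycle Bernoulli
    draws; serves as an independent stochastic oracle for ``run_cohort``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    n = len(ts) if horizon_cycles is None else min(horizon_cycles, len(ts))
    rng = np.random.default_rng(seed)
    state = np.zeros(n_patients, dtype=np.int8)  # 0 = PF, 1 = PD, 2 = dead
    pf = np.empty(n + 1)
    pd_ = np.empty(n + 1)
    dead = np.empty(n + 1)
    new_pd = np.zeros(n + 1)
    pf[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
    for t in range(n):
        u = rng.random(n_patients)
        progress = (state == 0) & (u < ts.p_pf_pd[t])
        die = (state == 1) & (u < ts.p_pd_death[t])
        state[progress] = 1
        state[die] = 2
        new_pd[t + 1] = np.mean(progress)
        pf[t + 1] = np.mean(state == 0)
        pd_[t + 1] = np.mean(state == 1)
        dead[t + 1] = np.mean(state == 2)
    return CohortTrace(pf=pf, pd=pd_, dead=dead, new_pd=new_pd)


def discount_factor(cycle_index, annual_rate: float, cycle_length_weeks: float):
    """(1 + rate) ^ (-elapsed years), with elapsed = cycle_index * cycle_length / 52."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    cycle_index = np.asarray(cycle_index, dtype=float)
    out = (1.0 + annual_rate) ** (-cycle_index * cycle_length_weeks / 52.0)
    return out.item() if out.ndim == 0 else out


def _occupancy(x: np.ndarray, half_cycle: bool) -> np.ndarray:
    """Per-cycle effective occupancy from boundary values."""
    return 0.5 * (x[:-1] + x[1:]) if half_cycle else x[:-1]


def accrue_qalys(trace: CohortTrace, utility_pf: float, utility_pd: float,
                 econ: EconomicParams, discounted: bool = True,
                 half_cycle: bool = True) -> tuple[float, float]:
    """Return (life_years, qalys) over the trace horizon."""
    years_per_cycle = econ.cycle_length_weeks / 52.0
    rate = econ.annual_discount if discounted else 0.0
    dfs = discount_factor(np.arange(trace.cycles), rate, econ.cycle_length_weeks)
    o_pf = _occupancy(trace.pf, half_cycle)
    o_pd = _occupancy(trace.pd, half_cycle)
    life_years = float(np.sum((o_pf + o_pd) * years_per_cycle * dfs))
    qalys = float(np.sum((o_pf * utility_pf + o_pd * utility_pd) * years_per_cycle * dfs))
    return life_years, qalys


def secondline_lump_cost(sd: StrategyDefinition, econ: EconomicParams) -> float:
    """Expected one-time second-line cost per PD entrant.

    Class mix x per-6-week unit cost x treatment duration; administration
    cost is added per active cycle for the intravenous classes (second-line
    chemotherapy and immunotherapy), not for oral targeted therapy.
    """
    total = 0.0
    for cls, mix in sd.secondline_mix.items():
        unit = econ.secondline_unit_costs.get(cls, 0.0)
        admin = econ.admin_cost_per_cycle if cls in ("chemo", "immunotherapy") else 0.0
        total += mix * econ.secondline_duration_cycles * (unit + admin)
    return total


def accrue_costs(trace: CohortTrace, sd: StrategyDefinition, econ: EconomicParams,
                 discounted: bool = True, half_cycle: bool = True) -> float:
    """Discounted lifetime cost of one strategy over the trace.

    While progression-free: administration cost every cycle, immunotherapy
    drug cost up to the 2-year cap, platinum-doublet cost during induction,
    then pemetrexed (non-squamous-weighted) and/or bevacizumab maintenance
    until progression.  While progressed: best supportive care per cycle.
    One-time: adverse-event lump at entry; expected second-line lump at each
    PD entry.
    """
    n = trace.cycles
    rate = econ.annual_discount if discounted else 0.0
    dfs = discount_factor(np.arange(n), rate, econ.cycle_length_weeks)
    t = np.arange(n)

    pf_cost = np.full(n, float(econ.admin_cost_per_cycle))
    pf_cost += np.where(t < sd.io_max_cycles, sd.io_cost_per_cycle, 0.0)
    pf_cost += np.where(t < sd.induction_chemo_cycles, sd.chemo_cost_per_cycle, 0.0)
    maintenance = sd.pem_maintenance_cost_per_cycle + sd.beva_cost_per_cycle
    pf_cost += np.where(t >= sd.induction_chemo_cycles, maintenance, 0.0)
    if econ.bsc_in_pf:
        pf_cost += econ.bsc_cost_per_cycle

    o_pf = _occupancy(trace.pf, half_cycle)
    o_pd = _occupancy(trace.pd, half_cycle)
    cost = float(np.sum(o_pf * pf_cost * dfs))
    cost += float(np.sum(o_pd * econ.bsc_cost_per_cycle * dfs))

    cost += sd.ae_lump_cost  # cycle 0, discount factor 1
    lump = secondline_lump_cost(sd, econ)
    if lump > 0:
        entry_dfs = discount_factor(np.arange(1, n + 1), rate, econ.cycle_length_weeks)
        cost += float(np.sum(trace.new_pd[1:] * lump * entry_dfs))
    if cost < -1e-9:
        raise ArithmeticError(f"negative accrued cost for {sd.name}: {cost}")
    return cost


def evaluate_strategy(sd: StrategyDefinition, reference: TransitionSchedule,
                      stratum, econ: EconomicParams,
                      half_cycle: bool = True) -> StrategyOutcome:
    """Build the strategy's arm from point hazard ratios, run the cohort to
    lifetime horizon, and accrue discounted and undiscounted outcomes."""
    stratum = as_stratum(stratum).value
    if sd.is_reference:
        arm = reference
    else:
        if stratum not in sd.hr_by_stratum:
            raise StrategyUnavailableError(
                f"strategy {sd.name!r} has no hazard ratios for stratum {stratum!r}"
            )
        hr = sd.hr_by_stratum[stratum]
        arm = build_arm_schedule(reference, hr["PFS"].point, hr["OS"].point)
    trace = run_cohort(arm, econ.horizon_cycles(), econ.stop_alive_fraction)
    ly_d, q_d = accrue_qalys(trace, sd.utility_pf, econ.utility_pd, econ,
                             discounted=True, half_cycle=half_cycle)
    ly_u, q_u = accrue_qalys(trace, sd.utility_pf, econ.utility_pd, econ,
                             discounted=False, half_cycle=half_cycle)
    return StrategyOutcome(
        strategy=sd.name,
        cost=accrue_costs(trace, sd, econ, discounted=True, half_cycle=half_cycle),
        life_years=ly_d,
        qalys=q_d,
        cost_undiscounted=accrue_costs(trace, sd, econ, discounted=False,
                                       half_cycle=half_cycle),
        life_years_undiscounted=ly_u,
        qalys_undiscounted=q_u,
    )
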