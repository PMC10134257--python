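"""End-to-end glue: curves -> calibrated schedules -> outcomes -> frontier."""

from __future__ import annotations

from .errors import CalibrationError
from .frontier import FrontierResult, compute_frontier
from .markov import evaluate_strategy
from .params import ParameterSet, as_stratum
from .survival import TransitionSchedule, calibrate_reference, extrapolate_schedule

#: cycles averaged when extrapolating beyond trial follow-up
DEFAULT_TAIL_WINDOW = 3


def reference_schedule(ps: ParameterSet, stratum,
                       tail_window: int = DEFAULT_TAIL_WINDOW) -> TransitionSchedule:
    """Calibrate the chemotherapy arm for a stratum and extrapolate to horizon."""
    stratum = as_stratum(stratum).value
    if stratum not in ps.curves:
        raise CalibrationError(
            f"no PFS/OS curves for stratum {stratum!r}; "
            "load a fixture study or point the config's curves section at files"
        )
    curves = ps.curves[stratum]
    ts = calibrate_reference(curves["PFS"], curves["OS"], ps.econ.cycle_length_weeks)
    return extrapolate_schedule(ts, ps.econ.horizon_cycles(), tail_window)


def evaluate_all(ps: ParameterSet, stratum, half_cycle: bool = True,
                 reference: TransitionSchedule | None = None) -> list:
    """Outcomes for every strategy available in the stratum (reference first)."""
    stratum = as_stratum(stratum).value
    ref = reference if reference is not None else reference_schedule(ps, stratum)
    strategies = sorted(ps.strategies_in(stratum), key=lambda sd: not sd.is_reference)
    return [evaluate_strategy(sd, ref, stratum, ps.econ, half_cycle)
            for sd in strategies]


def basecase(ps: ParameterSet, stratum, half_cycle: bool = True) -> FrontierResult:
    """The base-case analysis for one stratum: evaluate all strategies and
    compute the dominance frontier with pairwise ICERs."""
    return compute_frontier(evaluate_all(ps, stratum, half_cycle=half_cycle))
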