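"""Kaplan-Meier calibration: curves -> per-cycle transition probabilities.

The cohort model has two transitions: progression-free -> progressive disease
(driven directly by the PFS curve) and progressive disease -> death
(calibrated so the modelled overall survival tracks the OS curve).  Hazard
ratios move a probability between arms on the rate scale:

    r = -ln(1 - p)        p = 1 - exp(-r)        p' = 1 - (1 - p)^HR

Curves are treated as step functions (KM estimates are step functions), so
the survival value at a cycle boundary is the last digitised value at or
before it.  Beyond trial follow-up, per-cycle transition probabilities are
held at the mean of the last ``tail_window`` observed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import CalibrationError
from .params import SurvivalCurve

logger = logging.getLogger(__name__)

#: PD occupancy below which the calibrated death probability is carried forward
PD_OCCUPANCY_FLOOR = 1e-8

#: calibration fails validation when more than this fraction of cycles clip
MAX_CLIP_FRACTION = 0.05


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities for one treatment arm."""

    p_pf_pd: np.ndarray    # PF -> PD, one entry per cycle
    p_pd_death: np.ndarray  # PD -> death, one entry per cycle
    cycle_length_weeks: float = 6.0
    observed_cycles: int = 0   # cycles covered by trial follow-up
    clip_count: int = 0        # calibration cycles where q had to be clipped into [0,1]

    def __post_init__(self):
        self.p_pf_pd = np.asarray(self.p_pf_pd, dtype=float)
        self.p_pd_death = np.asarray(self.p_pd_death, dtype=float)
        if len(self.p_pf_pd) != len(self.p_pd_death):
            raise ValueError("p_pf_pd and p_pd_death must have equal length")
        for name, v in (("p_pf_pd", self.p_pf_pd), ("p_pd_death", self.p_pd_death)):
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name}: probabilities outside [0, 1]")

    def __len__(self) -> int:
        return len(self.p_pf_pd)

    @property
    def clip_fraction(self) -> float:
        return self.clip_count / max(self.observed_cycles, 1)


def prob_to_rate(p):
    """Per-cycle probability -> per-cycle rate, r = -ln(1 - p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("probability must satisfy 0 <= p < 1")
    out = -np.log1p(-p)
    return out.item() if out.ndim == 0 else out


def rate_to_prob(r):
    """Per-cycle rate -> per-cycle probability, p = 1 - exp(-r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be >= 0")
    out = -np.expm1(-r)
    return out.item() if out.ndim == 0 else out


def apply_hazard_ratio(p, hr):
    """Scale a per-cycle probability on the rate scale: p' = 1 - (1 - p)^hr."""
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("probability must satisfy 0 <= p < 1")
    out = -np.expm1(hr * np.log1p(-p))
    return out.item() if out.ndim == 0 else out


def boundary_survival(curve: SurvivalCurve, cycle_length_weeks: float,
                      n_cycles: int | None = None) -> np.ndarray:
    """Step-interpolated survival at cycle boundaries 0, 1, ..., n_cycles.

    By default ``n_cycles`` is the number of whole cycles the follow-up covers.
    """
    if n_cycles is None:
        n_cycles = int(np.floor(curve.times[-1] / cycle_length_weeks + 1e-9))
    t = np.arange(n_cycles + 1) * cycle_length_weeks
    return curve.at(t)


def pfs_to_transitions(pfs: SurvivalCurve, cycle_length_weeks: float) -> np.ndarray:
    """PF -> PD probabilities per cycle, p_t = [S(t) - S(t+1)] / S(t).

    Once the PFS curve reaches zero the probability is 0 thereafter (the PF
    compartment is empty).  Requires follow-up covering at least 2 cycles.
    """
    s = boundary_survival(pfs, cycle_length_weeks)
    if len(s) < 3:
        raise CalibrationError(
            f"PFS follow-up covers {len(s) - 1} cycle(s); at least 2 required"
        )
    p = np.zeros(len(s) - 1)
    nz = s[:-1] > 0
    p[nz] = (s[:-1][nz] - s[1:][nz]) / s[:-1][nz]
    return np.clip(p, 0.0, 1.0)


def calibrate_pd_death(os_curve: SurvivalCurve, pfs_curve: SurvivalCurve,
                       p_pf_pd: np.ndarray, cycle_length_weeks: float) -> tuple[np.ndarray, int]:
    """Calibrate PD -> death probabilities so modelled OS tracks the OS curve.

    Walks the cohort forward; at each cycle the death probability ``q_t`` is
    chosen so cumulative modelled deaths equal ``1 - S_OS(t+1)`` given the
    modelled PD occupancy.  When PD occupancy is ~0 the previous ``q`` is
    carried forward (0 initially); infeasible values are clipped into [0, 1]
    with a logged warning and counted.  Returns ``(q, clip_count)``.

    Boundaries where OS dips below PFS (a digitisation artifact; structurally
    impossible) are repaired by raising OS to PFS, with a warning.
    """
    p = np.asarray(p_pf_pd, dtype=float)
    n = len(p)
    s_os = boundary_survival(os_curve, cycle_length_weeks, n_cycles=n)
    s_pfs = boundary_survival(pfs_curve, cycle_length_weeks, n_cycles=n)
    if np.any(s_os < s_pfs - 1e-12):
        logger.warning("OS below PFS at %d boundaries; repaired by max(OS, PFS)",
                       int(np.sum(s_os < s_pfs - 1e-12)))
    s_os = np.maximum(s_os, s_pfs)

    q = np.zeros(n)
    pf, pd_occ, dead = 1.0, 0.0, 0.0
    prev_q = 0.0
    clips = 0
    for t in range(n):
        target_dead = 1.0 - s_os[t + 1]
        if pd_occ < PD_OCCUPANCY_FLOOR:
            qt = prev_q
        else:
            qt = (target_dead - dead) / pd_occ
            if qt < -1e-12 or qt > 1.0 + 1e-12:
                clips += 1
            qt = min(max(qt, 0.0), 1.0)
        q[t] = prev_q = qt
        new_pd = pf * p[t]
        dead += pd_occ * qt
        pd_occ = pd_occ * (1.0 - qt) + new_pd
        pf *= 1.0 - p[t]
    if clips:
        logger.warning("calibration clipped PD->death probability in %d/%d cycles", clips, n)
    return q, clips


def calibrate_reference(pfs: SurvivalCurve, os_curve: SurvivalCurve,
                        cycle_length_weeks: float = 6.0) -> TransitionSchedule:
    """Full reference-arm calibration: PFS/OS curves -> TransitionSchedule."""
    p = pfs_to_transitions(pfs, cycle_length_weeks)
    q, clips = calibrate_pd_death(os_curve, pfs, p, cycle_length_weeks)
    ts = TransitionSchedule(
        p_pf_pd=p, p_pd_death=q, cycle_length_weeks=cycle_length_weeks,
        observed_cycles=len(p), clip_count=clips,
    )
    if ts.clip_fraction > MAX_CLIP_FRACTION:
        raise CalibrationError(
            f"calibration clipped {clips}/{len(p)} cycles "
            f"(> {MAX_CLIP_FRACTION:.0%}); PFS/OS inputs are inconsistent"
        )
    return ts


def extrapolate_schedule(ts: TransitionSchedule, horizon_cycles: int,
                         tail_window: int = 3) -> TransitionSchedule:
    """Extend a schedule to ``horizon_cycles`` holding tail-mean probabilities.

    Cycles beyond trial follow-up get the arithmetic mean of the last
    ``tail_window`` observed values of each probability vector.  A horizon
    shorter than the observed span returns a truncated copy.
    """
    n_obs = ts.observed_cycles or len(ts)
    if not (1 <= tail_window <= n_obs):
        raise ValueError(f"tail_window must be in [1, {n_obs}]")
    if horizon_cycles <= n_obs:
        return replace(
            ts,
            p_pf_pd=ts.p_pf_pd[:horizon_cycles].copy(),
            p_pd_death=ts.p_pd_death[:horizon_cycles].copy(),
            observed_cycles=min(n_obs, horizon_cycles),
        )
    n_extra = horizon_cycles - n_obs
    tail_p = float(np.mean(ts.p_pf_pd[n_obs - tail_window:n_obs]))
    tail_q = float(np.mean(ts.p_pd_death[n_obs - tail_window:n_obs]))
    return replace(
        ts,
        p_pf_pd=np.concatenate([ts.p_pf_pd[:n_obs], np.full(n_extra, tail_p)]),
        p_pd_death=np.concatenate([ts.p_pd_death[:n_obs], np.full(n_extra, tail_q)]),
        observed_cycles=n_obs,
    )


def build_arm_schedule(reference: TransitionSchedule, hr_pfs: float,
                       hr_os: float) -> TransitionSchedule:
    """Apply PFS/OS hazard ratios cycle-wise to the reference schedule.

    The PFS hazard ratio scales the PF->PD transition and the OS hazard
    ratio scales the PD->death transition, both on the rate scale.
    """
    return replace(
        reference,
        p_pf_pd=apply_hazard_ratio(reference.p_pf_pd, hr_pfs),
        p_pd_death=apply_hazard_ratio(reference.p_pd_death, hr_os),
    )


def write_transition_schedule(ts: TransitionSchedule, path) -> None:
    """Emit ``cycle,p_pf_pd,p_pd_death,observed_flag`` delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("cycle,p_pf_pd,p_pd_death,observed_flag\n")
        for t in range(len(ts)):
            fh.write(f"{t},{float(ts.p_pf_pd[t])!r},{float(ts.p_pd_death[t])!r},"
                     f"{int(t < ts.observed_cycles)}\n")


def read_transition_schedule(path, cycle_length_weeks: float = 6.0) -> TransitionSchedule:
    data = np.genfromtxt(path, delimiter=",", names=True)
    return TransitionSchedule(
        p_pf_pd=np.atleast_1d(data["p_pf_pd"]),
        p_pd_death=np.atleast_1d(data["p_pd_death"]),
        cycle_length_weeks=cycle_length_weeks,
        observed_cycles=int(np.sum(np.atleast_1d(data["observed_flag"]))),
    )
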