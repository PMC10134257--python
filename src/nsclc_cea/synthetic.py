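"""Synthetic survival curves and complete fixture studies.

The published chemotherapy-arm PFS/OS coordinates this model was built
around are not deposited anywhere, so this module generates stand-ins with
the statistical structure the analysis assumes:

* :func:`make_survival_curve` — a (piecewise-)exponential curve with
  configurable medians, follow-up and optional multiplicative digitisation
  jitter.
* :func:`make_cohort_curves` — a PFS/OS pair generated by the same
  two-transition cohort process the calibration inverts (PFS hazard for
  PF->PD, a separate hazard for PD->death, OS = PF + PD occupancy).  On
  these, calibration recovers the truth exactly, which is what makes them
  suitable fidelity fixtures.
* :func:`make_fixture_study` — writes a loadable study directory: the
  shipped parameter table plus per-stratum synthetic curves and a manifest.

All fixture medians are synthetic: they loosely echo a platinum-doublet
chemotherapy arm (PFS median about 5.5 months, OS median about 14 months)
with mild stratum-to-stratum variation, and claim no trial fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import (ParameterSet, SurvivalCurve, builtin_parameter_set,
                     write_parameter_set)
from .survival import TransitionSchedule, rate_to_prob
from .markov import run_cohort

WEEKS_PER_MONTH = 52.0 / 12.0

#: synthetic per-stratum chemotherapy-arm medians, months (PFS, OS)
DEFAULT_STRATUM_MEDIANS = {
    "all": (5.5, 14.0),
    "lt1": (5.0, 12.0),
    "1to49": (5.2, 13.0),
    "ge50": (6.0, 15.0),
}

DEFAULT_FOLLOW_UP_WEEKS = 150.0  # ~3 years of trial follow-up (25 6-week cycles)


@dataclass
class PiecewiseExpSpec:
    """Spec for one synthetic curve: segment hazards, follow-up, sampling, noise."""

    hazards: list                 # per-week rates, one per segment
    breakpoints: list = field(default_factory=list)  # interior boundaries, weeks
    follow_up: float = DEFAULT_FOLLOW_UP_WEEKS
    sampling_interval: float = 6.0
    digitization_noise_sd: float = 0.0  # multiplicative, proportion
    seed: int = 0

    def validate(self) -> None:
        if any(h < 0 for h in self.hazards):
            raise ValueError("hazards must be >= 0")
        if len(self.hazards) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one hazard per segment "
                             "(len(hazards) == len(breakpoints) + 1)")
        bp = list(self.breakpoints)
        if any(b <= a for a, b in zip(bp, bp[1:])) or any(b <= 0 for b in bp):
            raise ValueError("breakpoints must be positive and increasing")
        if bp and self.follow_up < bp[-1]:
            raise ValueError("follow_up must cover the last breakpoint")
        if self.sampling_interval <= 0 or self.follow_up < 2 * self.sampling_interval:
            raise ValueError("follow_up must cover at least two sampling intervals")
        if self.digitization_noise_sd < 0:
            raise ValueError("digitization_noise_sd must be >= 0")


def cumulative_hazard(spec: PiecewiseExpSpec, t) -> np.ndarray:
    """Integral of the piecewise-constant hazard from 0 to each t (weeks)."""
    t = np.asarray(t, dtype=float)
    edges = np.concatenate([[0.0], np.asarray(spec.breakpoints, dtype=float),
                            [np.inf]])
    out = np.zeros_like(t)
    for i, h in enumerate(spec.hazards):
        lo, hi = edges[i], edges[i + 1]
        out += h * np.clip(t - lo, 0.0, hi - lo)
    return out


def make_survival_curve(spec: PiecewiseExpSpec, endpoint: str = "PFS") -> SurvivalCurve:
    """S(t) = exp(-cumulative hazard) at sampling intervals, plus optional
    multiplicative jitter truncated to keep the curve monotone in [0, 1]."""
    spec.validate()
    times = np.arange(0.0, spec.follow_up + 1e-9, spec.sampling_interval)
    surv = np.exp(-cumulative_hazard(spec, times))
    if spec.digitization_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = surv * (1.0 + rng.normal(0.0, spec.digitization_noise_sd, len(surv)))
        noisy[0] = 1.0
        noisy = np.clip(noisy, 0.0, 1.0)
        surv = np.minimum.accumulate(noisy)
    return SurvivalCurve(endpoint=endpoint, times=times, survival=surv)


def transition_schedule_from_hazards(pfs_spec: PiecewiseExpSpec,
                                     death_spec: PiecewiseExpSpec,
                                     cycle_length_weeks: float = 6.0) -> TransitionSchedule:
    """Exact per-cycle transition probabilities implied by two hazard specs."""
    n = int(np.floor(min(pfs_spec.follow_up, death_spec.follow_up)
                     / cycle_length_weeks + 1e-9))
    bounds = np.arange(n + 1) * cycle_length_weeks
    p = rate_to_prob(np.diff(cumulative_hazard(pfs_spec, bounds)))
    q = rate_to_prob(np.diff(cumulative_hazard(death_spec, bounds)))
    return TransitionSchedule(p_pf_pd=p, p_pd_death=q,
                              cycle_length_weeks=cycle_length_weeks,
                              observed_cycles=n)


def make_cohort_curves(pfs_spec: PiecewiseExpSpec, death_spec: PiecewiseExpSpec,
                       cycle_length_weeks: float = 6.0,
                       noise_sd: float = 0.0, seed: int = 0
                       ) -> tuple[SurvivalCurve, SurvivalCurve]:
    """PFS/OS pair generated by the cohort process the calibration assumes.

    PFS is the (piecewise-exponential) PF occupancy; OS is PF + PD occupancy
    under a piecewise-exponential PD->death hazard.  Noise-free output is
    exactly recoverable by calibration.  With noise, multiplicative jitter is
    applied and repaired to stay monotone in [0, 1] (OS kept >= PFS).
    """
    pfs_spec.validate()
    death_spec.validate()
    ts = transition_schedule_from_hazards(pfs_spec, death_spec, cycle_length_weeks)
    trace = run_cohort(ts)
    times = np.arange(len(ts) + 1) * cycle_length_weeks
    pfs_vals = trace.pf.copy()
    os_vals = (trace.pf + trace.pd).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for vals in (pfs_vals, os_vals):
            vals *= 1.0 + rng.normal(0.0, noise_sd, len(vals))
            vals[0] = 1.0
            np.clip(vals, 0.0, 1.0, out=vals)
            np.minimum.accumulate(vals, out=vals)
        np.maximum(os_vals, pfs_vals, out=os_vals)
    return (SurvivalCurve("PFS", times, pfs_vals),
            SurvivalCurve("OS", times, os_vals))


def _stratum_specs(median_pfs_months: float, median_os_months: float,
                   follow_up: float) -> tuple[PiecewiseExpSpec, PiecewiseExpSpec]:
    """Single-segment hazards hitting the PFS median exactly; the PD->death
    hazard is set from the OS-PFS median gap (the resulting OS median is
    approximate, which is fine for a synthetic stand-in)."""
    if median_os_months <= median_pfs_months:
        raise ValueError("OS median must exceed PFS median")
    lam = np.log(2.0) / (median_pfs_months * WEEKS_PER_MONTH)
    mu = np.log(2.0) / ((median_os_months - median_pfs_months) * WEEKS_PER_MONTH)
    return (PiecewiseExpSpec(hazards=[lam], follow_up=follow_up),
            PiecewiseExpSpec(hazards=[mu], follow_up=follow_up))


def make_fixture_study(out_dir, stratum_medians: dict | None = None,
                       overrides: dict | None = None, seed: int = 0,
                       noise_sd: float = 0.0,
                       follow_up_weeks: float = DEFAULT_FOLLOW_UP_WEEKS) -> Path:
    """Write a complete, loadable synthetic study; returns the config path.

    The parameter table is the shipped one (optionally with dotted-path
    ``overrides`` applied); curves are cohort-consistent synthetics per
    stratum.  Deterministic under ``seed``.
    """
    from .params import apply_overrides  # local import to avoid cycle at import time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    medians = dict(DEFAULT_STRATUM_MEDIANS)
    if stratum_medians:
        medians.update(stratum_medians)
    ps = builtin_parameter_set()
    if overrides:
        ps = apply_overrides(ps, overrides)
    manifest = {"seed": seed, "noise_sd": noise_sd,
                "follow_up_weeks": follow_up_weeks, "stratum_medians": {},
                "synthetic": True}
    for i, (stratum, (m_pfs, m_os)) in enumerate(sorted(medians.items())):
        pfs_spec, death_spec = _stratum_specs(m_pfs, m_os, follow_up_weeks)
        pfs, os_curve = make_cohort_curves(
            pfs_spec, death_spec, cycle_length_weeks=ps.econ.cycle_length_weeks,
            noise_sd=noise_sd, seed=seed + i)
        ps.curves[stratum] = {"PFS": pfs, "OS": os_curve}
        manifest["stratum_medians"][stratum] = {
            "pfs_months": m_pfs, "os_months": m_os,
            "pfs_hazard_per_week": pfs_spec.hazards[0],
            "pd_death_hazard_per_week": death_spec.hazards[0],
        }
    config_path = write_parameter_set(ps, out_dir / "study.yaml")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return config_path


def fixture_parameter_set(seed: int = 0, noise_sd: float = 0.0,
                          stratum_medians: dict | None = None,
                          overrides: dict | None = None) -> ParameterSet:
    """In-memory fixture study (no files): shipped parameters + synthetic curves."""
    from .params import apply_overrides

    ps = builtin_parameter_set()
    if overrides:
        ps = apply_overrides(ps, overrides)
    medians = dict(DEFAULT_STRATUM_MEDIANS)
    if stratum_medians:
        medians.update(stratum_medians)
    for i, (stratum, (m_pfs, m_os)) in enumerate(sorted(medians.items())):
        pfs_spec, death_spec = _stratum_specs(m_pfs, m_os, DEFAULT_FOLLOW_UP_WEEKS)
        pfs, os_curve = make_cohort_curves(
            pfs_spec, death_spec, cycle_length_weeks=ps.econ.cycle_length_weeks,
            noise_sd=noise_sd, seed=seed + i)
        ps.curves[stratum] = {"PFS": pfs, "OS": os_curve}
    return ps
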