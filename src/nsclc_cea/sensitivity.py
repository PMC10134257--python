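"""Sensitivity machinery: HR-bound scenarios, one-way DSA, threshold pricing,
probabilistic sensitivity analysis and acceptability curves.

PSA draws each parameter from its declared distribution (Beta for utilities
and second-line proportions, Gamma for costs, Dirichlet for the histology
split) and hazard ratios from a lognormal reconstructed from the 95% CI
(location = ln point, scale = [ln hi - ln lo] / 3.92).  PFS and OS hazard
ratios of the same strategy are sampled independently (no joint distribution
is available).  The cost-effectiveness acceptability curve reports, per
willingness-to-pay value, the fraction of draws in which each strategy has
the greatest net monetary benefit (ties split equally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as prm
from .errors import (NonMonotoneError, NSCLCCEAError, ThresholdNotFoundError)
from .frontier import FrontierResult, compute_frontier, icer, net_monetary_benefit
from .markov import evaluate_strategy
from .params import (ParameterSet, apply_overrides, as_stratum, get_parameter,
                     set_parameter)
from .pipeline import evaluate_all, reference_schedule

#: default willingness-to-pay grid, USD/QALY (anchored at the 150k threshold)
DEFAULT_WTP_GRID = tuple(range(0, 300_001, 10_000))

Z95 = 3.92  # width of a 95% CI in standard normal units (2 x 1.96)


@dataclass
class TornadoEntry:
    """One-way sensitivity of a pairwise ICER to a single parameter."""

    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass
class PSADraw:
    """One Monte-Carlo iteration: sampled overrides and per-strategy outcomes."""

    iteration: int
    overrides: dict
    outcomes: dict  # strategy -> StrategyOutcome


@dataclass
class CEACurve:
    """Probability each strategy is cost-effective across a WTP grid."""

    wtp: np.ndarray
    strategies: list
    probabilities: np.ndarray  # shape (len(wtp), len(strategies))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, w in enumerate(self.wtp):
            for j, s in enumerate(self.strategies):
                rows.append({"wtp": w, "strategy": s,
                             "probability": self.probabilities[i, j]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario analysis at the HR confidence bounds

def scenario_hr_bounds(ps: ParameterSet, stratum, bound: str = "point",
                       half_cycle: bool = True) -> FrontierResult:
    """Re-evaluate every strategy with all hazard ratios set simultaneously to
    their lower or upper 95% CI bound (or the point estimate = base case)."""
    if bound not in ("lower", "upper", "point"):
        raise ValueError("bound must be 'lower', 'upper' or 'point'")
    stratum = as_stratum(stratum).value
    ps = ps.copy()
    attr = {"lower": "low", "upper": "high", "point": "point"}[bound]
    for sd in ps.strategies_in(stratum):
        if sd.is_reference:
            continue
        if stratum not in sd.hr_by_stratum:
            raise NSCLCCEAError(f"strategy {sd.name} lacks HRs in stratum {stratum}")
        for spec in sd.hr_by_stratum[stratum].values():
            spec.point = getattr(spec, attr)
    outcomes = evaluate_all(ps, stratum, half_cycle=half_cycle)
    return compute_frontier(outcomes)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity

def _pairwise_icer(ps: ParameterSet, strategy: str, comparator: str, stratum,
                   effect: str = "qaly", half_cycle: bool = True) -> float:
    ref = reference_schedule(ps, stratum)
    hi = evaluate_strategy(ps.strategies[strategy], ref, stratum, ps.econ, half_cycle)
    lo = evaluate_strategy(ps.strategies[comparator], ref, stratum, ps.econ, half_cycle)
    return icer(hi, lo, effect)


def one_way_dsa(ps: ParameterSet, target_comparison: tuple, stratum,
                parameter_path: str, low: float, high: float,
                effect: str = "qaly") -> TornadoEntry:
    """ICER of (strategy vs comparator) with one parameter at each range end,
    everything else held at base case."""
    if low > high:
        raise ValueError(f"{parameter_path}: low {low} > high {high}")
    strategy, comparator = target_comparison
    get_parameter(ps, parameter_path)  # raises UnknownParameterError early
    icers = {}
    for label, value in (("low", low), ("high", high)):
        ps_v = set_parameter(ps, parameter_path, value)
        icers[label] = _pairwise_icer(ps_v, strategy, comparator, stratum, effect)
    return TornadoEntry(parameter=parameter_path, low=low, high=high,
                        icer_low=icers["low"], icer_high=icers["high"])


def tornado(entries: list) -> list:
    """Sort one-way DSA entries by ICER span, widest bar first."""
    if not entries:
        raise ValueError("tornado needs at least one entry")
    return sorted(entries, key=lambda e: e.span, reverse=True)


def tornado_frame(entries: list) -> pd.DataFrame:
    return pd.DataFrame(
        [{"parameter": e.parameter, "low": e.low, "high": e.high,
          "low_icer": e.icer_low, "high_icer": e.icer_high, "span": e.span}
         for e in tornado(entries)]
    )


def run_dsa(ps: ParameterSet, target_comparison: tuple, stratum,
            parameter_paths: list | None = None) -> list:
    """One-way DSA over the declared ranges (default: every dsa_ranges entry)."""
    paths = parameter_paths if parameter_paths is not None else list(ps.dsa_ranges)
    entries = []
    for path in paths:
        low, high = ps.dsa_ranges[path]
        entries.append(one_way_dsa(ps, target_comparison, stratum, path, low, high))
    return tornado(entries)


# ---------------------------------------------------------------------------
# threshold pricing

def threshold_price(ps: ParameterSet, strategy: str, comparator: str, stratum,
                    parameter_path: str, wtp: float, tol: float = 1.0,
                    max_iter: int = 100) -> float:
    """Bisect a per-cycle cost parameter until the pairwise ICER equals wtp.

    Returns the parameter value at which |ICER - wtp| <= ``tol`` (USD).
    Raises :class:`ThresholdNotFoundError` if even a zero cost leaves the
    ICER above wtp, and :class:`NonMonotoneError` if the ICER does not
    decrease as the cost parameter decreases.
    """
    base = get_parameter(ps, parameter_path)
    f = lambda c: _pairwise_icer(set_parameter(ps, parameter_path, c),
                                 strategy, comparator, stratum)
    icer_base = f(base)
    if abs(icer_base - wtp) <= tol or icer_base <= wtp:
        return base
    icer_zero = f(0.0)
    if icer_zero >= icer_base:
        raise NonMonotoneError(
            f"ICER does not decrease with {parameter_path} "
            f"({icer_zero:.0f} at 0 vs {icer_base:.0f} at base)"
        )
    if icer_zero > wtp:
        raise ThresholdNotFoundError(
            f"ICER is {icer_zero:.0f} > wtp {wtp:.0f} even at zero {parameter_path}"
        )
    lo, hi = 0.0, base  # f(lo) <= wtp <= f(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val - wtp) <= tol:
            return mid
        if val > wtp:
            hi = mid
        else:
            lo = mid
    raise ThresholdNotFoundError(
        f"bisection on {parameter_path} did not reach |ICER - wtp| <= {tol}"
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def _sample_one(spec: prm.DistributionSpec, base: float, rng) -> float:
    if spec.family == "fixed":
        return base
    if spec.family == "beta":
        a, b = spec.params
        return float(rng.beta(a, b))
    if spec.family == "gamma":
        shape, scale = spec.params
        return float(rng.gamma(shape) * scale)
    if spec.family == "dirichlet":
        return float(rng.dirichlet(np.asarray(spec.params, dtype=float))[0])
    if spec.family == "lognormal_from_ci":
        point, lo, hi = spec.params
        sigma = (np.log(hi) - np.log(lo)) / Z95
        return float(rng.lognormal(np.log(point), sigma))
    raise ValueError(f"unknown distribution family {spec.family!r}")


def sample_parameters(ps: ParameterSet, rng, stratum=None) -> dict:
    """Draw one override map: declared distributions plus the hazard ratios.

    Hazard ratios are always sampled lognormal-from-CI; when ``stratum`` is
    given only that stratum's HRs are drawn.  Second-line mixes that sum
    above 1 after sampling are renormalised.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    overrides: dict = {}
    for path, spec in ps.distributions.items():
        overrides[path] = _sample_one(spec, get_parameter(ps, path), rng)
    strata = [as_stratum(stratum).value] if stratum is not None else list(prm.STRATA)
    for sd in ps.strategies.values():
        for s in strata:
            for ep, spec in sd.hr_by_stratum.get(s, {}).items():
                hr_spec = prm.DistributionSpec(
                    "lognormal_from_ci", (spec.point, spec.low, spec.high))
                overrides[f"hr.{sd.name}.{s}.{ep.lower()}"] = _sample_one(
                    hr_spec, spec.point, rng)
    # renormalise any sampled second-line mix exceeding a total of 1
    for name, sd in ps.strategies.items():
        paths = [f"strategy.{name}.secondline_mix.{cls}" for cls in sd.secondline_mix]
        sampled = [p for p in paths if p in overrides]
        total = sum(overrides[p] for p in sampled)
        if sampled and total > 1.0:
            for p in sampled:
                overrides[p] /= total
    return overrides


def run_psa(ps: ParameterSet, stratum, n_iterations: int, seed: int,
            half_cycle: bool = True) -> list:
    """Monte-Carlo PSA: sample, rebuild arms and costs, evaluate all strategies.

    Deterministic under (seed, n_iterations).  The reference transition
    schedule is recomputed once (curves are not sampled); hazard ratios,
    costs, utilities and mixes vary per iteration.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    stratum = as_stratum(stratum).value
    rng = np.random.default_rng(seed)
    ref = reference_schedule(ps, stratum)
    draws = []
    for i in range(n_iterations):
        overrides = sample_parameters(ps, rng, stratum)
        try:
            ps_i = apply_overrides(ps, overrides)
            outcomes = {
                sd.name: evaluate_strategy(sd, ref, stratum, ps_i.econ, half_cycle)
                for sd in ps_i.strategies_in(stratum)
            }
        except NSCLCCEAError as exc:
            raise NSCLCCEAError(f"PSA iteration {i}: {exc}") from exc
        draws.append(PSADraw(iteration=i, overrides=overrides, outcomes=outcomes))
    return draws


def ceac(draws: list, wtp_grid=DEFAULT_WTP_GRID) -> CEACurve:
    """Cost-effectiveness acceptability curve from PSA draws."""
    if not draws:
        raise ValueError("ceac needs at least one draw")
    strategies = list(draws[0].outcomes)
    wtp = np.asarray(wtp_grid, dtype=float)
    prob = np.zeros((len(wtp), len(strategies)))
    for draw in draws:
        nmb = np.array([[net_monetary_benefit(draw.outcomes[s], w) for s in strategies]
                        for w in wtp])
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-9  # ties split equally
        prob += winners / winners.sum(axis=1, keepdims=True)
    prob /= len(draws)
    return CEACurve(wtp=wtp, strategies=strategies, probabilities=prob)


def psa_frame(draws: list) -> pd.DataFrame:
    rows = []
    for draw in draws:
        for name, o in draw.outcomes.items():
            rows.append({"iteration": draw.iteration, "strategy": name,
                         "cost": o.cost, "life_years": o.life_years,
                         "qalys": o.qalys})
    return pd.DataFrame(rows)
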