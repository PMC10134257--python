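"""Cost-effectiveness frontier: strong/extended dominance and pairwise ICERs.

Strategies are rank-ordered by cost.  A strategy is *strongly dominated* if
an alternative is cheaper with at least as many QALYs (equal-cost ties go to
the higher-effect strategy).  Survivors are screened for *extended (weak)
dominance*: sequential ICERs along the cost-ordered survivors must be
strictly increasing; any strategy whose incremental cost per QALY exceeds
that of the next costlier survivor is removed, iterating to a fixed point.
ICERs are reported against the next costliest undominated strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import UndefinedICERError
from .markov import StrategyOutcome

LABEL_REFERENCE = "reference"
LABEL_FRONTIER = "on_frontier"
LABEL_STRONG = "strongly_dominated"
LABEL_WEAK = "weakly_dominated"


def _effect(outcome: StrategyOutcome, effect: str) -> float:
    if effect == "qaly":
        return outcome.qalys
    if effect == "life_year":
        return outcome.life_years
    raise ValueError(f"effect must be 'qaly' or 'life_year', got {effect!r}")


def icer(higher: StrategyOutcome, lower: StrategyOutcome, effect: str = "qaly") -> float:
    """Incremental cost per unit of incremental effect."""
    d_eff = _effect(higher, effect) - _effect(lower, effect)
    if d_eff == 0.0:
        raise UndefinedICERError(
            f"{higher.strategy} and {lower.strategy} have equal {effect}s"
        )
    return (higher.cost - lower.cost) / d_eff


def net_monetary_benefit(outcome: StrategyOutcome, wtp: float) -> float:
    """wtp x QALYs - cost; the frontier-equivalent decision criterion."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * outcome.qalys - outcome.cost


@dataclass
class FrontierResult:
    """Dominance labels and frontier ICERs for one stratum's strategy set."""

    outcomes: list = field(default_factory=list)   # ordered by cost ascending
    labels: dict = field(default_factory=dict)     # strategy -> label
    icer_qaly: dict = field(default_factory=dict)  # frontier strategy -> USD/QALY
    icer_ly: dict = field(default_factory=dict)    # frontier strategy -> USD/LY
    comparator: dict = field(default_factory=dict)  # frontier strategy -> comparator name

    @property
    def frontier(self) -> list:
        return [o.strategy for o in self.outcomes
                if self.labels[o.strategy] in (LABEL_REFERENCE, LABEL_FRONTIER)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            rows.append({
                "strategy": o.strategy,
                "cost": o.cost,
                "life_years": o.life_years,
                "qalys": o.qalys,
                "icer_ly": self.icer_ly.get(o.strategy),
                "icer_qaly": self.icer_qaly.get(o.strategy),
                "label": self.labels[o.strategy],
            })
        return pd.DataFrame(rows)


def compute_frontier(outcomes: list, effect: str = "qaly") -> FrontierResult:
    """Label every strategy and compute frontier ICERs (per QALY and per life
    year, both against the comparator chosen on the requested effect scale)."""
    if len(outcomes) < 2:
        raise ValueError("frontier analysis needs at least 2 strategies")
    order = sorted(outcomes, key=lambda o: (o.cost, -_effect(o, effect)))
    eff = {o.strategy: _effect(o, effect) for o in order}
    labels: dict = {}

    for s in order:
        for o in order:
            if o is s:
                continue
            if (o.cost < s.cost and eff[o.strategy] >= eff[s.strategy]) or (
                    o.cost == s.cost and eff[o.strategy] > eff[s.strategy]):
                labels[s.strategy] = LABEL_STRONG
                break

    survivors = [o for o in order if o.strategy not in labels]
    # identical (cost, effect) duplicates: keep the first
    seen = set()
    kept = []
    for o in survivors:
        key = (o.cost, eff[o.strategy])
        if key in seen:
            labels[o.strategy] = LABEL_WEAK
        else:
            seen.add(key)
            kept.append(o)
    survivors = kept

    while len(survivors) > 2:
        icers = [icer(survivors[j], survivors[j - 1], effect)
                 for j in range(1, len(survivors))]
        removed = False
        for j in range(1, len(icers)):
            if icers[j - 1] >= icers[j]:  # s_j less efficient than the next survivor
                labels[survivors[j].strategy] = LABEL_WEAK
                del survivors[j]
                removed = True
                break
        if not removed:
            break

    result = FrontierResult(outcomes=order, labels=labels)
    for i, o in enumerate(survivors):
        if i == 0:
            labels[o.strategy] = LABEL_REFERENCE
        else:
            labels[o.strategy] = LABEL_FRONTIER
            comparator = survivors[i - 1]
            result.comparator[o.strategy] = comparator.strategy
            result.icer_qaly[o.strategy] = icer(o, comparator, "qaly")
            try:
                result.icer_ly[o.strategy] = icer(o, comparator, "life_year")
            except UndefinedICERError:
                result.icer_ly[o.strategy] = None
    # post-hoc invariant: frontier ICERs strictly increase with cost
    seq = [result.icer_qaly[o.strategy] for o in survivors[1:]] if effect == "qaly" \
        else [result.icer_ly[o.strategy] for o in survivors[1:]]
    assert all(a < b for a, b in zip(seq, seq[1:])), \
        "frontier ICERs must strictly increase along the frontier"
    return result
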