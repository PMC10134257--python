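"""Base-case cost-effectiveness frontier per PD-L1 stratum.

Evaluates every available strategy (discounted lifetime cost, life years,
QALYs), labels dominated strategies and prints ICERs against the next
costliest undominated comparator — the shape of a standard base-case table.
"""

import nsclc_cea as n

ps = n.fixture_parameter_set(seed=1)

for stratum in ("all", "lt1", "1to49", "ge50"):
    result = n.basecase(ps, stratum)
    print(f"\n=== PD-L1 stratum: {stratum} ===")
    print(result.to_frame().round(2).to_string(index=False))
# 'strongly_dominated' = costlier and less effective than an alternative;
# 'weakly_dominated'   = removed by extended dominance (its incremental cost
# per QALY exceeds that of a more effective strategy further up the frontier).
# ICERs are USD per discounted QALY / life year.
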