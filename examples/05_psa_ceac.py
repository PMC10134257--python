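"""Probabilistic sensitivity analysis and acceptability curves.

Draws every uncertain parameter from its declared distribution (utilities
Beta, costs Gamma, histology Dirichlet, hazard ratios lognormal-from-CI),
re-evaluates all strategies per draw, and reports the probability each
strategy is cost-effective as willingness-to-pay varies.
"""

import nsclc_cea as n
from nsclc_cea.sensitivity import ceac, run_psa

ps = n.fixture_parameter_set(seed=1)
draws = run_psa(ps, "ge50", n_iterations=1000, seed=42)
curve = ceac(draws)

i = list(curve.wtp).index(150_000.0)
print("P(cost-effective) at $150,000/QALY, PD-L1 >= 50%:")
for s, p in sorted(zip(curve.strategies, curve.probabilities[i]),
                   key=lambda x: -x[1]):
    print(f"  {s:18s} {p:6.1%}")
# The probability is the fraction of draws in which the strategy has the
# greatest net monetary benefit (wtp x QALYs - cost) at that threshold.
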