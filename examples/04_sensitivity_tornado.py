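"""One-way deterministic sensitivity: which parameters move the ICER most?

Varies each declared parameter across its plausible range (one at a time,
everything else at base case) for pembro-chemo vs chemotherapy and prints
the tornado table, widest bar first.  Also finds the drug price at which a
strategy would meet the $150,000/QALY willingness-to-pay threshold.
"""

import nsclc_cea as n
from nsclc_cea.sensitivity import run_dsa, threshold_price, tornado_frame

ps = n.fixture_parameter_set(seed=1)
comparison = ("pembro_chemo", "chemotherapy")

entries = run_dsa(ps, comparison, "all")
print(tornado_frame(entries).head(10).round(0).to_string(index=False))
# span = |ICER at high end - ICER at low end|, USD/QALY.  The compared
# immunotherapy's own drug cost and utility dominate, as expected.

price = threshold_price(ps, "pembro_chemo", "chemotherapy", "all",
                        "drug_costs.pembrolizumab", wtp=150_000)
base = n.get_parameter(ps, "drug_costs.pembrolizumab")
print(f"\npembrolizumab price for pembro-chemo to hit $150k/QALY: "
      f"${price:,.0f} per 6 weeks (base ${base:,.0f})")
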