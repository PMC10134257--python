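"""Build a synthetic study and inspect the calibrated chemotherapy arm.

The published chemotherapy-arm PFS/OS coordinates are not deposited, so the
package generates stand-in curves with the exact structure the model
assumes.  This script writes a study directory, calibrates the reference
arm, and prints the first per-cycle transition probabilities.
"""

from pathlib import Path

import nsclc_cea as n

out = Path("scratch/example_study")
config = n.make_fixture_study(out, seed=1)
print(f"study written to {config}")

ps = n.load_parameter_set(config)
ts = n.reference_schedule(ps, "all")
print(f"observed cycles: {ts.observed_cycles} (6-week each), "
      f"extrapolated to {len(ts)} cycles (~30 years)")
print("cycle  P(PF->PD)  P(PD->death)")
for t in range(5):
    print(f"{t:5d}  {ts.p_pf_pd[t]:9.4f}  {ts.p_pd_death[t]:12.4f}")
# The PF->PD column is read straight off the PFS curve; the PD->death column
# is calibrated so the modelled overall survival tracks the OS curve.
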