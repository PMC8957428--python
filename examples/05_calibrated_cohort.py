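"""Calibrate stage profiles to published SDNN set-points and verify.

The generator's stage profiles are calibrated by bisection so mean extracted
SDNN matches the winter-training stage set-points (52.31 / 55.93 / 69.67 ms,
early / middle / late).  Prints the achieved means over fresh subjects.
"""

import numpy as np

from hrvcdet import default_stage_profiles, simulate_rr, time_domain

profiles = default_stage_profiles(calibrate=True)
print(f"{'stage':>8} {'target SDNN':>12} {'achieved':>10}")
for j, p in enumerate(profiles):
    vals = [time_domain(simulate_rr(p, 1000 + j * 100 + i)).sdnn for i in range(50)]
    print(f"{p.stage:>8} {p.target_sdnn:12.2f} {np.mean(vals):10.2f}")
print("\nachieved means track the set-points and preserve the")
print("early < middle < late variability ordering.")
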