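"""The default anomalous-signal to solvability calibration.

The curve is a logistic anchored at the empirical behavior of real SAD data
sets: about half succeed at a signal of 9, few below ~7, most above ~13.
Width and midpoint are configuration, not physics — recalibrate with your
own success statistics if you have them.
"""

import sadsignal as ss

calib = ss.SolvabilityCalibration()
print(f"calibration: midpoint s50 = {calib.s50}, width = {calib.width}")
print(f"solved criterion: >= {calib.site_fraction:.0%} of sites within "
      f"{calib.distance_cutoff} A")
print()
print("  S_ano   P(solved)")
for s in (3, 5, 7, 9, 11, 13, 15, 20):
    print(f"  {s:5.1f}   {ss.solve_probability(s, calib):9.3f}")
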