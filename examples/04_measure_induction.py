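"""Quantify a gene-expression induction with background-corrected ratios.

The movie carries an inducible reporter (channel 1, stepping 6-fold at
frame 15, emulating a carbon-source switch) and a constitutive reference
(channel 2).  Measuring both over the tracked selections, subtracting the
per-frame background, and averaging the per-cell green-to-red ratio per
frame recovers the programmed induction fold.
"""

import numpy as np

import mycotrack as mt
from mycotrack.benchmark import analyze_simulated, corner_background

stacks, truth = mt.simulate(mt.SimConfig(seed=1, n_frames=30))
project = analyze_simulated(stacks, truth)

project.set_background(corner_background(project.shape))
n = project.measure(channels=["ch1", "ch2"])
print(f"measured {n} selections on the original images")

tc = project.ratio_timecourse("ch1", "ch2")
print("frame  t(min)  mean ratio   sd     n")
for f in sorted(tc):
    mean, sd, n_cells, _ = tc[f]
    print(f"  {f:2d}   {f * 10:4d}    {mean:6.3f}   {sd:5.3f}   {n_cells}")

baseline = np.mean([tc[f][0] for f in tc if f < 15])
plateau = np.mean([tc[f][0] for f in tc if f >= 20])
print(f"baseline {baseline:.3f}, plateau {plateau:.3f}, "
      f"fold induction {plateau / baseline:.2f} (programmed: 6)")
# The ratio normalises reporter signal by global expression capacity, so
# the step at frame 15 and its fold are recovered despite tracking noise.
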