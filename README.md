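# mycotrack

Semi-automated segmentation, tracking, measurement and lineage
visualization for time-lapse movies of mycobacteria and other
difficult-to-segment rod-shaped bacteria.

Mycobacterial microcolonies are hard on standard single-cell pipelines:
neighbouring cells pack tightly with no visible edge between them,
division produces no constriction at first (so there is no reliable
automatic division cue), and cells are long, bent rods rather than the
short capsules most bacterial segmenters assume. `mycotrack` follows the
semi-automated strategy built for exactly this regime: the analyst
outlines each initial cell once and annotates division events; everything
else — frame-to-frame propagation of every cell outline, intensity
measurements, background correction, derived statistics, storage and
lineage-tree figures — is automatic and scriptable.

## The tracking algorithm

Cells are assumed to be worm-shaped with near-constant width *w*, to grow
almost exclusively at their poles, and to change only slightly between
frames. Each frame is processed as:

1. **Edge map** — 3×3 Sobel gradient magnitude, auto-thresholded
   (IsoData intermeans by default; Otsu/mean/triangle/Li/Yen available),
   thinned to one-pixel contours with the classical two-subiteration
   (Zhang–Suen) thinning.
2. **Skeletonise** — the cell's previous selection is thinned to its
   skeleton.
3. **Re-centre** — the skeleton grows into the *adjusted area*: pixels
   within the configured distance *w* of a detected edge and near the
   previous skeleton, with edge contours acting as barriers. This snaps a
   drifted selection back onto the cell body.
4. **Elongate poles** — beyond each skeleton endpoint, a half-disc of
   radius *p* oriented away from the cell is probed; pixels passing the
   same edge-distance test are admitted nearest-first until the projected
   area would exceed the previous area plus *a*.
5. **Reconstruct** — a disk of radius *w* is smeared along the adjusted
   skeleton and admitted pole pixels, clipped at the detected contour.

Cells are processed round-robin in alphabetical order; contested pixels
belong to the cell that claimed them first, and a cell never expands into
territory the previous frame assigned to a neighbour. Defaults are
*w* = 3, *p* = 10, *a* = 35 pixels. Division is deliberately manual: the
analyst names the dividing cell and supplies the two daughter outlines;
daughters are named by appending A/B (cell A divides into AA and AB; AB
into ABA and ABB), so `len(name) - 1` is the generation.

Everything lands in one SQLite file — frames, shifts, cells, run-length
encoded outlines, events, long-format measurements — queryable with
read-only SQL and exportable as CSV. Lineage trees are rendered as SVG
with time on the vertical axis and any two measured variables mapped to
branch width and branch color.

A first-class synthetic-movie generator (`mycotrack.simulate`) produces
ground-truthed colonies reproducing the hard features above (invisible
contact edges, no division site, slight change per frame, step-induced
reporter + constitutive reference channels), which is what the tests and
the acceptance script score against.

## Worked example

```python
import mycotrack as mt
from mycotrack.benchmark import (analyze_simulated, corner_background,
                                 score_segmentation)

stacks, truth = mt.simulate(mt.SimConfig(seed=1, n_frames=30))
project = analyze_simulated(stacks, truth)   # seed, track, divide
score = score_segmentation(project, truth)
print(score.n_auto, round(score.mean_iou, 3), score.swaps)

project.set_background(corner_background(project.shape))
project.measure(channels=["ch1", "ch2"])
tc = project.ratio_timecourse("ch1", "ch2")
print(round(tc[0][0], 3), round(tc[29][0], 3))
```

prints

```
96 0.827 0
0.297 1.791
```

96 outlines were propagated automatically with a mean overlap (IoU) of
0.827 against the known truth masks and zero identity swaps — no
selection ever wandered onto a neighbouring cell. The background-corrected
green-to-red ratio rises from 0.297 before the simulated medium switch to
1.79 after it, a 6-fold induction, matching the programmed reporter step.
The scripts in `examples/` walk through each capability (simulation,
drift registration, tracking, measurement, tree rendering, SQL export)
with commented output; `mycotrack --help` exposes the same workflow as a
command line for file-based projects.

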