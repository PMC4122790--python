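# Methods

This note records the models, parameter choices and numerical decisions
behind `mycotrack`, in the order the pipeline runs. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Image preparation

Each channel is an ordered image sequence (frame order = last integer
group in the file name, ties lexicographic). Originals keep their native
bit depth and are the only images ever measured; an 8-bit working copy
drives tracking and display. The 8-bit conversion is a *per-sequence*
global min–max linear rescale — per-frame rescaling would erase intensity
dynamics across frames (e.g. an induction step) from the working copy.
Excluded frames (out of focus, shutter failures) stay in the stack but
are skipped by segmentation and measurement; propagation bridges the gap
by seeding from the last usable frame.

## Registration

Stage drift is modelled as an integer whole-frame translation between
successive frames. The estimator scores all `(2·max_shift+1)²` candidate
shifts by the Pearson correlation of the overlapping region (a flat patch
scores 0) and breaks ties toward the smallest `|dy|+|dx|`, then smallest
`dy`, then `dx`, so constant images register as (0, 0). Pairwise shifts
are accumulated relative to frame 0 and the same correction is applied to
every channel; vacated pixels are filled with the frame's modal value. A
correlation peak below 0.2 (configurable) contributes a zero shift and a
warning rather than a wild jump. Sub-pixel and rotational registration
are out of scope. On simulated phase frames the estimator recovers known
shifts ≤ 3 px exactly in 100/100 trials at 8-bit Gaussian noise σ = 5
(recomputed by the acceptance script).

## Edge map

Sobel 3×3 gradients are computed with edge replication at the borders and
the magnitude is rescaled linearly to 0–255. IsoData thresholding is
implemented from its defining fixed point
`t = floor((mean(v ≤ t) + mean(v > t)) / 2)`, initialised at the midpoint
of the occupied histogram range and iterated with a cycle guard; a
single-valued image is a degenerate-histogram error. The alternative
methods (Otsu, mean, triangle, Li, Yen) come from scikit-image and are
offered through the same interface plus a side-by-side gallery. The
binary edges are thinned with the two-subiteration parallel thinning
(both passes evaluate their deletion conditions on a snapshot); the
vectorised implementation is checked pixel-for-pixel against a literal
per-pixel transcription of the published rule tables on 200 random blobs.

## Selection propagation

The three parameters are pixels: cell width `w = 3`, maximum pole
elongation `p = 10`, maximum area increase `a = 35` (the platform's
standard values at 0.129 µm/px). `w` is interpreted as the disk *radius*
used both in the edge-distance test and in reconstruction, giving a
reconstructed tube ≈ 2w+1 px ≈ 0.9 µm wide, consistent with mycobacteria
at this pixel size; whether the original treats it as radius or diameter
is not stated, so this is a documented choice, configurable per run.

Three numerical decisions matter here and were made for stated geometric
reasons:

- **Distance is measured to the detected contour, with a +1 allowance.**
  The thinned Sobel contour of a dark cell with a bright halo lies on the
  halo side, about one pixel outside the true boundary, so a pixel within
  `w` of the cell edge is within `w + 1` of the contour line. With the
  literal `≤ w` test a perfectly centred skeleton in a cell of nominal
  width `2w` sits 3.1–3.6 px from the contour and the cell is lost
  immediately.
- **Edges are barriers; growth is 4-connected.** An 8-connected thinned
  curve blocks 4-connected flood exactly (digital topology duality);
  8-connected growth would leak through every diagonal staircase of the
  contour. This applies to the adjusted-area growth, to the pole probe
  (a nearest-first flood from each endpoint, still confined to the
  oriented half-disc of radius `p`), and to the final reconstruction,
  which is clipped to the edge-bounded region(s) around the cell-body
  skeleton. The pole probe therefore stops at the cell's current contour
  instead of running past the pole on pure distance grounds.
- **The area budget counts what survives the clip.** The projected
  reconstructed area that the `a` cap constrains is evaluated over the
  same edge-bounded region, not over the raw dilation (whose spill across
  the contour is removed anyway). The cap is additionally enforced as a
  hard final trim (drop pixels farthest from the guide, deterministic
  tie-break), so `area(new) ≤ area(prev) + a` holds on every propagation
  by construction.

Pole direction at each endpoint is the unit vector from the skeleton
pixel 5 steps inward (graph distance along the skeleton; configurable;
endpoints closer than 5 steps to a branch use the farthest reachable
pixel). A single-pixel skeleton has no direction and probes the full
disc. Cells are processed round-robin in alphabetical order within each
frame; pixels claimed by an earlier cell, pixels of selections already
fixed on the frame (freshly annotated daughters), and pixels the
*previous* frame assigned to another cell are all unavailable. The last
rule extends first-come ownership across frames: the joint area between
cells with no detectable border is assigned once and retained, which is
what prevents an alphabetically earlier cell from consuming its sibling
at `a` px/frame across an invisible septum. Division is never inferred:
the analyst annotates the dividing cell and supplies both daughter
outlines, which become manual selections that subsequent propagation
seeds from — as does any manual correction of a mis-segmented frame.

## Measurements

Statistics (area, mean, SD, min, max, integrated = mean × area) are taken
over the stored pixel sets on the original images, optionally after
morphological erosion with a Euclidean disk (an erosion that empties the
mask is an error). Cell length is the skeleton pixel count × pixel size,
accurate to about ±w near the poles. A user-defined cell-free region
yields per-frame, per-channel background means; `mean_corrected` rows
(mean − background) are materialised whenever background means exist and
are simply absent otherwise — never zero-filled. Two growth rates are
reported because the platform's exact formula is not fixed: the linear
elongation rate (least-squares slope of length vs time, µm/h) and the
exponential area rate (slope of ln area vs time, 1/h). The ratio
time-course divides background-corrected means per cell per frame,
excludes (and counts) cells with non-positive denominator, then averages
across cells per frame; the same computation ships as a named SQL query.

## Datastore

One SQLite file holds the whole project: frame metadata and shifts,
cells, ROIs as row-wise run-length-encoded text (`r:c+len,...`, exact
round-trip), a frame-independent background region, long-format
measurements `(cell, frame, channel, variable, value)` so new variables
need no schema change, and an event log in which every state-changing
operation records its full parameter set. Foreign keys are enforced;
deleting a cell cascades to its subtree, ROIs and measurements. Upserts
are written as `ON CONFLICT DO UPDATE` — `INSERT OR REPLACE` would fire
the self-referencing cascade and silently delete a replaced cell's
descendants. Ad-hoc SQL runs on a read-only connection (write statements
fail in the engine); in-memory projects guard the live connection with an
authorizer instead. CSV export writes an RFC-4180 file with a header row
and full float precision.

## Lineage trees

Layout is recursive and deterministic: leaves get unit lanes in
A-before-B order, an internal cell sits at the midpoint of its daughters'
lanes, and the vertical axis is time in minutes, so a branch's vertical
extent is exactly the cell's lifetime (a divided cell ends at the
division instant, `time(end_frame + 1)`). Sibling subtrees occupy
disjoint lane intervals, so the layout is planar; the test suite verifies
zero crossings by brute force up to four complete generations. Branches
are drawn as one SVG line element per frame interval; width is an affine
map of one sampled variable, color a colormap of another (per-frame
piecewise-constant styling — the sampling grain is the frame, a choice),
with values outside the domain clamped, missing samples drawn neutral
grey and reported, a color-bar/width legend, dashed horizontal event
annotations, and open/filled end markers for censored/dead cells. SVG is
emitted with the standard-library XML tools; tests read the primitives
back to verify time and style fidelity.

## Synthetic movies

The generator defines the study conditions and exists to reproduce the
features that make real mycobacterial movies hard, with known truth.
Cells are constant-width tubes around dense poly-line backbones; growth
appends at both poles (strictly polar, no intercalation) with small
angular wander (σ = 0.05 rad/frame); division triggers at a cell-specific
threshold and cuts uniformly within the middle 20% of the backbone, with
daughters named A (first half) and B. Defaults, chosen once for realism
at the platform's pixel size: 256 px canvas at 0.129 µm/px, 30 frames at
10 min, 2 initial cells of 4.5/3.5 µm, width 0.8 µm, elongation
1.2 µm/h (≈ 3 h doubling for a 3→6 µm cycle), division at 6.0 ± 0.4 µm.
An exponential-area mode programs the *area* trajectory
`A(t) = A₀·exp(rt)` (default r = 0.4 h⁻¹) and derives backbone length
from the tube geometry, so measured areas should recover r directly.

Packing uses anisotropic local repulsion: rods slide along their axis
(≤ 1 px/frame) but barely move sideways (≤ 0.2 px/frame, net
≤ 1 px/frame), modelling rod-monolayer mechanics and keeping the movie in
the slight-change regime the tracker assumes. Truth masks are assigned by
nearest backbone within the tube radius, with ownership hysteresis
(cytoplasm does not swap between touching cells); masks are therefore
disjoint and abutting. In the default movie ≥ 95% of frame-to-frame truth
transitions have IoU ≥ 0.8 and all exceed 0.7 — a hard 0.8 minimum is
geometrically impossible for a 6-px-wide rod, since a single ~1 px
passive displacement already costs ~0.25 of the overlap of a short cell.

Phase contrast is rendered as dark interior (60) + bright halo (185) on a
120 background with additive Gaussian noise (σ = 4, clipped to 8 bits; no
shot-noise model — sufficient for algorithm testing). Each contact pair
between touching cells draws once whether its shared boundary is visible:
with probability 0.3 it shows *no* edge contrast (the Figure-style
challenge), otherwise a faint bright line — matching the algorithm's
stated operating assumption that most juxtaposed cells show at least some
visible edge. The inducible channel renders a per-cell level of 30 AU
stepping 6-fold at frame 15 (a carbon-source switch); the constitutive
channel renders 100 AU; both carry a shared per-cell expression factor
(global machinery, σ = 5%) which the ratio normalises away, plus σ = 2 AU
pixel noise over a background of 10. `corrupt()` degrades one frame
(defocus with dynamic-range collapse, or full intensity collapse) to
fixture the needs-attention / manual-correction workflow.

What passing on this generator does and does not show: it validates the
propagation geometry, the ownership rules, the measurement chain and the
bookkeeping under the paper-stated challenges, at realistic SNR. It does
not model phase-contrast optics (no PSF), V-snapping division
morphology, photobleaching, illumination gradients or focus drift — so
real movies will need more manual correction than the synthetic fraction
(~11% of selections here, all of them seeds and division outlines)
suggests.

## Problem sizes

The default study movie is 30 frames of 256² px with 2 initial cells
growing to ~12 (≥ 5 divisions); oracle checks run on 200 random 64² blobs
(thinning), 102 histograms (IsoData), 100 noisy frame pairs
(registration) and 1000 random masks (datastore round-trip). These sizes
make the whole acceptance computation a matter of seconds while keeping
every per-cell statistic in the dozens-to-hundreds regime.

## Known limitations

Order dependence is inherent to round-robin processing when no border is
detectable; the mitigations (previous-frame ownership, fixed-mask claims)
bound but do not remove it. Skeleton-based length underestimates near the
poles by about the tube radius. The area cap is absolute pixels per
frame, so it should be rescaled when the pixel size or frame interval
changes materially. Identity across an excluded-frame gap relies on the
slight-change assumption holding over the doubled interval.
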