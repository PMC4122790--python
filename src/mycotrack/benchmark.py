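"""Evaluation harness: run the semi-automated workflow on synthetic movies
and score it against ground truth.

The platform is semi-automated by design: selection propagation is
automatic, division events are user-annotated.  :func:`analyze_simulated`
emulates that workflow on a generated movie — initial cells and division
masks come from the ground truth (standing in for the user), everything
else is tracked automatically — and the scoring helpers measure overlap
with the truth masks, identity stability and the per-step area constraint.

The module also carries deliberately naive reference implementations
(:func:`zhang_suen_reference`, :func:`isodata_reference`) used as
independent oracles: literal per-pixel transcriptions of the published
rules, sharing no code with the vectorised implementations they check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masks import PixelMask
from .project import Project
from .segmentation import SegParams
from .stack import FrameStack
from .store import ProjectDB
from .synthetic import GroundTruth


# ---------------------------------------------------------------------------
# Workflow emulation
# ---------------------------------------------------------------------------

def analyze_simulated(stacks: dict[str, FrameStack], truth: GroundTruth,
                      db_path=":memory:", params: SegParams | None = None,
                      ) -> Project:
    """Track a simulated movie with truth-supplied division annotations.

    Initial cells are seeded from the frame-0 truth masks; at every truth
    division frame the parent's division is annotated with the truth
    daughter masks (the user's job in the real workflow); all other
    selections are propagated automatically.
    """
    project = Project(ProjectDB(db_path), stacks, params=params)
    for name, mask in sorted(truth.masks_at(0).items()):
        if len(name) == 1:
            project.create_initial_cell(name, mask, 0)
    by_frame: dict[int, list[str]] = {}
    for parent, frame in truth.divisions():
        by_frame.setdefault(frame, []).append(parent)

    active = sorted(n for n in truth.label_of if len(n) == 1)
    for f in range(1, truth.n_frames):
        for parent in by_frame.get(f, []):
            project.record_division(parent, f,
                                    truth.mask(parent + "A", f),
                                    truth.mask(parent + "B", f))
            active.remove(parent)
            active += [parent + "A", parent + "B"]
        project.segment_range(sorted(active), range(f, f + 1), "phase")
    return project


@dataclass
class SegmentationScore:
    ious: list[float]
    swaps: int
    n_auto: int
    n_manual: int
    n_missing: int
    area_violations: int  # propagation steps breaking area(new)<=area(prev)+a

    @property
    def mean_iou(self) -> float:
        return float(np.mean(self.ious)) if self.ious else float("nan")

    @property
    def min_iou(self) -> float:
        return float(np.min(self.ious)) if self.ious else float("nan")


def score_segmentation(project: Project, truth: GroundTruth,
                       max_area_increase: int = 35) -> SegmentationScore:
    """Score tracked selections against the truth masks.

    IoU is computed for every automatically propagated selection against
    the same cell's truth mask; an identity swap is a tracked mask that
    overlaps some other truth cell more than its own.  Also audits the
    per-step area constraint on every propagation.
    """
    db = project.db
    ious: list[float] = []
    swaps = 0
    n_auto = n_manual = n_missing = 0
    violations = 0
    for f in range(truth.n_frames):
        tmasks = truth.masks_at(f)
        for name in sorted(truth.label_of):
            rec = truth.lineage.cells[name]
            end = rec.end_frame if rec.end_frame is not None else \
                truth.n_frames - 1
            if not rec.birth_frame <= f <= end:
                continue
            if not db.has_roi(name, f):
                n_missing += 1
                continue
            mask, prov = db.load_roi(name, f)
            if prov == "manual":
                n_manual += 1
                continue
            n_auto += 1
            t = tmasks.get(name)
            if t is None:
                continue
            inter = len(mask.pixels & t.pixels)
            union = len(mask.pixels | t.pixels)
            ious.append(inter / union)
            overlaps = {n: len(mask.pixels & tm.pixels)
                        for n, tm in tmasks.items()}
            if max(overlaps, key=overlaps.get) != name:
                swaps += 1
            if f > 0 and db.has_roi(name, f - 1):
                prev, _ = db.load_roi(name, f - 1)
                if mask.area > prev.area + max_area_increase:
                    violations += 1
    return SegmentationScore(ious=ious, swaps=swaps, n_auto=n_auto,
                             n_manual=n_manual, n_missing=n_missing,
                             area_violations=violations)


# ---------------------------------------------------------------------------
# Independent oracles (literal transcriptions; no shared code with the
# implementations they check)
# ---------------------------------------------------------------------------

def zhang_suen_reference(binary: np.ndarray) -> np.ndarray:
    """Per-pixel transcription of the two-subiteration thinning rules."""
    img = binary.astype(bool).copy()
    h, w = img.shape

    def neighbours(r, c):
        # P2..P9 clockwise from north
        def at(rr, cc):
            return img[rr, cc] if 0 <= rr < h and 0 <= cc < w else False
        return [at(r - 1, c), at(r - 1, c + 1), at(r, c + 1),
                at(r + 1, c + 1), at(r + 1, c), at(r + 1, c - 1),
                at(r, c - 1), at(r - 1, c - 1)]

    while True:
        deleted_any = False
        for phase in (0, 1):
            to_delete = []
            for r in range(h):
                for c in range(w):
                    if not img[r, c]:
                        continue
                    nb = neighbours(r, c)
                    b = sum(nb)
                    if not 2 <= b <= 6:
                        continue
                    a = sum(1 for i in range(8)
                            if not nb[i] and nb[(i + 1) % 8])
                    if a != 1:
                        continue
                    p2, _, p4, _, p6, _, p8, _ = nb
                    if phase == 0:
                        if (p2 and p4 and p6) or (p4 and p6 and p8):
                            continue
                    else:
                        if (p2 and p4 and p8) or (p2 and p6 and p8):
                            continue
                    to_delete.append((r, c))
            for r, c in to_delete:
                img[r, c] = False
            if to_delete:
                deleted_any = True
        if not deleted_any:
            return img


def isodata_reference(values: np.ndarray) -> list[int]:
    """All thresholds t in 0..254 satisfying the intermeans fixed point.

    Exhaustive scan: t is a fixed point iff both classes {v <= t} and
    {v > t} are nonempty and t == floor((mean_low + mean_high) / 2).
    """
    values = np.asarray(values).ravel()
    out = []
    for t in range(255):
        low = values[values <= t]
        high = values[values > t]
        if low.size == 0 or high.size == 0:
            continue
        if t == int((low.mean() + high.mean()) // 2):
            out.append(t)
    return out


def random_blob(rng: np.random.Generator, size: int = 64,
                n_seeds: int = 6, n_grow: int = 350) -> np.ndarray:
    """Random connected-ish binary blob for thinning comparisons."""
    img = np.zeros((size, size), dtype=bool)
    pts = [(int(rng.integers(8, size - 8)), int(rng.integers(8, size - 8)))
           for _ in range(n_seeds)]
    frontier = list(pts)
    for r, c in pts:
        img[r, c] = True
    for _ in range(n_grow):
        r, c = frontier[int(rng.integers(len(frontier)))]
        dr, dc = int(rng.integers(-1, 2)), int(rng.integers(-1, 2))
        rr, cc = min(max(r + dr, 1), size - 2), min(max(c + dc, 1), size - 2)
        img[rr, cc] = True
        frontier.append((rr, cc))
    return img


def euclidean_disk_reference(radius: int) -> set[tuple[int, int]]:
    """Brute-force enumeration of offsets with dr^2 + dc^2 <= radius^2."""
    return {(dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if dr * dr + dc * dc <= radius * radius}


def registration_recovery(seed: int, trials: int = 100,
                          noise_sd: float = 5.0, shift_range: int = 3,
                          max_shift: int = 5) -> float:
    """Fraction of trials with exact shift recovery under Gaussian noise.

    Each trial displaces a synthetic phase frame by a random integer shift
    up to ``shift_range`` pixels, adds 8-bit Gaussian noise to both frames
    and checks that the estimated shift matches exactly.
    """
    from .registration import ShiftVector, estimate_shift, shift_image
    from .synthetic import SimConfig, simulate

    rng = np.random.default_rng(seed)
    stacks, _ = simulate(SimConfig(seed=seed, n_frames=1))
    base = stacks["phase"].images8[0].astype(np.float64)
    hits = 0
    for _ in range(trials):
        dy = int(rng.integers(-shift_range, shift_range + 1))
        dx = int(rng.integers(-shift_range, shift_range + 1))
        moved = shift_image(base.astype(np.uint8), ShiftVector(dy, dx))
        ref = np.clip(base + rng.normal(0, noise_sd, base.shape),
                      0, 255).astype(np.uint8)
        mov = np.clip(moved + rng.normal(0, noise_sd, base.shape),
                      0, 255).astype(np.uint8)
        est = estimate_shift(ref, mov, max_shift)
        hits += (est.dy, est.dx) == (dy, dx)
    return hits / trials


def random_mask(rng: np.random.Generator, shape=(64, 64),
                n_pixels: int = 200) -> PixelMask:
    rr = rng.integers(0, shape[0], size=n_pixels)
    cc = rng.integers(0, shape[1], size=n_pixels)
    return PixelMask(frozenset(zip(rr.tolist(), cc.tolist())))


# ---------------------------------------------------------------------------
# Measurement recovery
# ---------------------------------------------------------------------------

def growth_rate_recovery(seed: int, rate_per_h: float = 0.4,
                         n_frames: int = 20) -> float:
    """Recover a programmed exponential area growth rate (1/h).

    Simulates a single non-dividing cell whose area grows exponentially,
    measures its truth ROIs through the measurement pipeline and returns
    the fitted exponential area rate.
    """
    from .synthetic import SimConfig, simulate

    cfg = SimConfig(seed=seed, n_frames=n_frames, initial_cells=1,
                    growth_mode="exponential_area",
                    area_exp_rate_per_h=rate_per_h,
                    divisions_enabled=False, initial_length_um=(3.0,))
    stacks, truth = simulate(cfg)
    project = Project(ProjectDB(":memory:"), stacks)
    project.create_initial_cell("A", truth.mask("A", 0), 0)
    for f in range(1, truth.n_frames):
        project.db.save_roi("A", truth.mask("A", f), provenance="manual")
    project.measure(channels=["ch1", "ch2"])
    return project.growth_rate("A")["area_exp_per_h"]


def corner_background(shape=(256, 256), lo: int = 5,
                      hi: int = 25) -> PixelMask:
    """Cell-free background block in the top-left canvas corner."""
    return PixelMask(frozenset(
        (r, c) for r in range(lo, hi) for c in range(lo, hi)), 0)


def induction_recovery(project: Project, truth: GroundTruth,
                       switch_frame: int = 15,
                       settle: int = 5) -> tuple[float, float, float]:
    """Measure the step-induction fold on a tracked movie.

    Background-corrects both fluorescence channels, runs the green-to-red
    ratio time-course and returns (baseline mean ratio, plateau mean ratio,
    plateau/baseline fold); ``settle`` frames after the switch are skipped
    before the plateau window.
    """
    project.set_background(corner_background(project.shape))
    project.measure(channels=["ch1", "ch2"])
    tc = project.ratio_timecourse("ch1", "ch2")
    baseline = float(np.mean(
        [tc[f][0] for f in tc if f < switch_frame]))
    plateau = float(np.mean(
        [tc[f][0] for f in tc if f >= switch_frame + settle]))
    return baseline, plateau, plateau / baseline
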