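"""Ground-truthed synthetic time-lapse movies of mycobacteria-like cells.

The generator emulates the features that make real mycobacterial movies
hard to segment: closely packed worm-shaped cells with no visible edge
between most touching neighbours, no clear division site (daughters abut
end to end), and only slight change from frame to frame.  Cells are
modelled as constant-width tubes around elongating poly-line backbones;
growth is strictly polar and division splits the backbone near its
midpoint.  Phase-contrast is rendered as a dark tube interior with a
bright halo plus Gaussian noise; two fluorescence channels carry a step-
induced reporter (channel 1) and a constitutive reference (channel 2).

Every frame's labelled truth masks, the truth lineage and the per-cell
programmed lengths, areas and fluorescence levels are returned alongside
the images, so tests can score segmentation and measurement recovery
against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError
from .lineage import Lineage
from .masks import PixelMask
from .stack import FrameStack


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic movie (seed fully determines it)."""

    seed: int = 1
    image_size: int = 256
    pixel_size_um: float = 0.129
    n_frames: int = 30
    dt_min: float = 10.0
    initial_cells: int = 2
    cell_width_um: float = 0.8
    elongation_rate_um_per_h: float = 1.2
    growth_mode: str = "linear"          # "linear" | "exponential_area"
    area_exp_rate_per_h: float = 0.4     # exponential_area mode only
    division_length_um: float = 6.0
    division_jitter_um: float = 0.4
    initial_length_um: tuple[float, ...] = (4.5, 3.5)
    divisions_enabled: bool = True
    bend_sd_rad: float = 0.05            # per-frame angular wander per pole
    # phase rendering (8-bit levels)
    phase_background: float = 120.0
    phase_interior: float = 60.0
    halo_strength: float = 65.0          # halo = background + halo_strength
    noise_sd: float = 4.0
    contact_edge_fraction: float = 0.3   # P(shared boundary shows NO edge)
    # fluorescence
    switch_frame: int = 15
    induction_fold: float = 6.0
    baseline_level: float = 30.0
    constitutive_level: float = 100.0
    fluor_background: float = 10.0
    fluor_noise_sd: float = 2.0

    def __post_init__(self):
        if self.induction_fold < 1:
            raise ParameterError("induction_fold must be >= 1")
        if self.elongation_rate_um_per_h < 0 or self.area_exp_rate_per_h < 0:
            raise ParameterError("rates must be >= 0")
        if self.growth_mode not in ("linear", "exponential_area"):
            raise ParameterError(f"unknown growth_mode {self.growth_mode!r}")


@dataclass
class GroundTruth:
    """Per-frame labelled masks plus the truth lineage and variables."""

    labels: list[np.ndarray]
    label_of: dict[str, int]
    lineage: Lineage
    length_um: dict[tuple[str, int], float]
    area_px: dict[tuple[str, int], int]
    fluor_level: dict[tuple[str, int, str], float]
    truncated: bool = False
    n_frames: int = 0

    def mask(self, name: str, frame: int) -> PixelMask:
        return PixelMask.from_array(
            self.labels[frame] == self.label_of[name], frame)

    def masks_at(self, frame: int) -> dict[str, PixelMask]:
        out = {}
        for name, lab in self.label_of.items():
            arr = self.labels[frame] == lab
            if arr.any():
                out[name] = PixelMask.from_array(arr, frame)
        return out

    def divisions(self) -> list[tuple[str, int]]:
        """(parent, division frame) pairs, in chronological order."""
        out = [(rec.name, rec.end_frame + 1)
               for rec in self.lineage.cells.values()
               if rec.fate == "divided"]
        return sorted(out, key=lambda t: (t[1], t[0]))


class _Cell:
    """Simulation state of one live cell: a dense backbone poly-line."""

    def __init__(self, name: str, pts: np.ndarray, birth_frame: int,
                 div_len_px: float, expr_factor: float, ch1_factor: float):
        self.name = name
        self.pts = pts                  # (N, 2) float (row, col), ~0.5 px apart
        self.birth_frame = birth_frame
        self.div_len_px = div_len_px
        self.expr_factor = expr_factor  # global machinery, affects both channels
        self.ch1_factor = ch1_factor    # reporter-specific variation

    @property
    def length_px(self) -> float:
        return float(np.linalg.norm(np.diff(self.pts, axis=0),
                                    axis=1).sum())


def _resample(pts: np.ndarray, spacing: float = 0.5) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(math.ceil(total / spacing)) + 1, 2)
    s = np.linspace(0.0, total, n)
    return np.stack([np.interp(s, arc, pts[:, 0]),
                     np.interp(s, arc, pts[:, 1])], axis=1)


def _rot(v: np.ndarray, theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _extend(cell: _Cell, d_each: float, rng,
            bend_sd: float = 0.05) -> None:
    """Polar growth: extend both poles by ``d_each`` pixels."""
    if d_each <= 0:
        return
    pts = cell.pts
    for pole in (0, 1):
        if pole == 0:
            direction = pts[0] - pts[1]
        else:
            direction = pts[-1] - pts[-2]
        direction = direction / (np.linalg.norm(direction) + 1e-12)
        direction = _rot(direction, rng.normal(0.0, bend_sd))
        tip = (pts[0] if pole == 0 else pts[-1]) + direction * d_each
        pts = np.vstack([tip, pts]) if pole == 0 else np.vstack([pts, tip])
    cell.pts = _resample(pts)


def _repel(cells: list[_Cell], width_px: float,
           perp_cap_px: float = 0.2, para_cap_px: float = 1.0,
           net_cap_px: float = 1.0) -> None:
    """Anisotropic local repulsion so tubes abut without interpenetrating.

    Rod-shaped cells in a packed monolayer slide easily along their long
    axis (growth-driven pushing) but hardly move sideways, so the
    displacement a cell receives per frame is decomposed along its axis:
    the lengthwise component may reach ``para_cap_px``, the lateral one is
    damped to ``perp_cap_px``, and the net per-frame displacement is capped
    at ``net_cap_px`` — keeping packing compatible with the
    slight-change-per-frame regime the tracking algorithm assumes.
    """
    net = [0.0] * len(cells)
    for _ in range(4):
        moved = False
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                a, b = cells[i].pts[::4], cells[j].pts[::4]
                d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
                k = int(np.argmin(d2))
                dmin = math.sqrt(d2.flat[k])
                if dmin >= 0.9 * width_px:
                    continue
                ia, ib = divmod(k, b.shape[0])
                v = b[ib] - a[ia]
                nv = np.linalg.norm(v)
                v = v / nv if nv > 1e-9 else np.array([1.0, 0.0])
                want = min(0.5 * (0.9 * width_px - dmin), 0.5)
                for idx, sign in ((i, -1.0), (j, 1.0)):
                    cell = cells[idx]
                    push = min(want, max(0.0, net_cap_px - net[idx]))
                    if push <= 0:
                        continue
                    p = sign * v * push
                    axis = cell.pts[-1] - cell.pts[0]
                    axis = axis / (np.linalg.norm(axis) + 1e-12)
                    para = np.dot(p, axis) * axis
                    perp = p - para
                    pn = float(np.linalg.norm(perp))
                    if pn > perp_cap_px:
                        perp = perp * (perp_cap_px / pn)
                    pa = float(np.linalg.norm(para))
                    if pa > para_cap_px:
                        para = para * (para_cap_px / pa)
                    disp = para + perp
                    cell.pts = cell.pts + disp
                    net[idx] += float(np.linalg.norm(disp))
                    moved = True
        if not moved:
            break


def _rasterize(cells: list[_Cell], shape: tuple[int, int],
               radius_px: float, label_of: dict[str, int],
               prev_labels: np.ndarray | None = None) -> np.ndarray:
    """Nearest-backbone ownership with hysteresis: disjoint, abutting masks.

    A contested pixel (within radius of several backbones) keeps its
    previous owner as long as it stays within that cell's radius —
    cytoplasm does not swap between touching cells — and otherwise goes to
    the nearest backbone.
    """
    dists = []
    order = sorted(cells, key=lambda c: c.name)
    for cell in order:
        raster = np.zeros(shape, dtype=bool)
        ij = np.round(cell.pts).astype(int)
        ij[:, 0] = np.clip(ij[:, 0], 0, shape[0] - 1)
        ij[:, 1] = np.clip(ij[:, 1], 0, shape[1] - 1)
        raster[ij[:, 0], ij[:, 1]] = True
        dists.append(ndi.distance_transform_edt(~raster))
    stack_d = np.stack(dists)
    nearest = np.argmin(stack_d, axis=0)
    within = np.min(stack_d, axis=0) <= radius_px
    labels = np.zeros(shape, dtype=np.int16)
    for idx, cell in enumerate(order):
        labels[(nearest == idx) & within] = label_of[cell.name]
    if prev_labels is not None:
        for idx, cell in enumerate(order):
            lab = label_of[cell.name]
            keep = (prev_labels == lab) & (stack_d[idx] <= radius_px) \
                & within
            labels[keep] = lab
    return labels


def _contact_pairs(labels: np.ndarray) -> set[tuple[int, int]]:
    pairs = set()
    for sh in ((0, 1), (1, 0)):
        a = labels[:labels.shape[0] - sh[0], :labels.shape[1] - sh[1]]
        b = labels[sh[0]:, sh[1]:]
        touch = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[touch].tolist(), b[touch].tolist()):
            pairs.add((min(x, y), max(x, y)))
    return pairs


def _render_phase(labels: np.ndarray, cfg: SimConfig, rng,
                  visible_contacts: set[tuple[int, int]]) -> np.ndarray:
    union = labels > 0
    img = np.full(labels.shape, cfg.phase_background, dtype=np.float64)
    img[union] = cfg.phase_interior
    halo = ndi.binary_dilation(union, iterations=2) & ~union
    img[halo] = cfg.phase_background + cfg.halo_strength
    # faint bright line on the (minority of) visible contact boundaries
    if visible_contacts:
        for la, lb in visible_contacts:
            a = labels == la
            b = labels == lb
            line = (ndi.binary_dilation(a) & b) | (ndi.binary_dilation(b) & a)
            img[line] = cfg.phase_background + 0.6 * cfg.halo_strength
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _render_fluor(labels: np.ndarray, levels: dict[int, float],
                  cfg: SimConfig, rng) -> np.ndarray:
    img = np.full(labels.shape, cfg.fluor_background, dtype=np.float64)
    for lab, level in levels.items():
        img[labels == lab] += level
    img += rng.normal(0.0, cfg.fluor_noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def simulate(config: SimConfig) -> tuple[dict[str, FrameStack], GroundTruth]:
    """Generate the movie: phase + 2 fluorescence stacks and ground truth.

    The colony stops early (``truth.truncated``) if it reaches the canvas
    border before ``n_frames``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.image_size, cfg.image_size)
    px = cfg.pixel_size_um
    radius_px = cfg.cell_width_um / px / 2.0
    width_px = 2.0 * radius_px
    rate_px = cfg.elongation_rate_um_per_h / 60.0 * cfg.dt_min / px

    def div_len_px() -> float:
        return (cfg.division_length_um
                + rng.normal(0.0, cfg.division_jitter_um)) / px

    lineage = Lineage()
    label_of: dict[str, int] = {}
    next_label = [1]

    def register(name: str) -> int:
        label_of[name] = next_label[0]
        next_label[0] += 1
        return label_of[name]

    # --- initial placement: parallel-ish rods near the canvas centre
    cells: list[_Cell] = []
    h = cfg.image_size
    for i in range(cfg.initial_cells):
        name = chr(ord("A") + i)
        L_um = cfg.initial_length_um[i % len(cfg.initial_length_um)]
        L = L_um / px
        row = h / 2.0 + (i - (cfg.initial_cells - 1) / 2.0) * 2.5 * width_px
        angle = rng.uniform(-0.18, 0.18)
        d = np.array([math.sin(angle), math.cos(angle)])
        c0 = np.array([row, h / 2.0]) - d * L / 2.0
        pts = _resample(np.stack([c0, c0 + d * L]))
        cells.append(_Cell(name, pts, 0, div_len_px(),
                           expr_factor=float(rng.normal(1.0, 0.05)),
                           ch1_factor=float(rng.normal(1.0, 0.03))))
        register(name)
        rec_mask = PixelMask(frozenset({(0, 0)}))  # placeholder, area>0
        lineage.create_initial_cell(name, rec_mask, 0)

    area0_px2 = {c.name: 2 * radius_px * c.length_px + math.pi * radius_px ** 2
                 for c in cells}

    truth = GroundTruth(labels=[], label_of=label_of, lineage=lineage,
                        length_um={}, area_px={}, fluor_level={})
    phase_frames: list[np.ndarray] = []
    ch1_frames: list[np.ndarray] = []
    ch2_frames: list[np.ndarray] = []
    contact_visibility: dict[tuple[int, int], bool] = {}

    for f in range(cfg.n_frames):
        if f > 0:
            for cell in cells:
                if cfg.growth_mode == "linear":
                    d_each = rate_px / 2.0
                else:
                    t_h = f * cfg.dt_min / 60.0
                    target_area = area0_px2[cell.name] * math.exp(
                        cfg.area_exp_rate_per_h * t_h)
                    target_len = (target_area - math.pi * radius_px ** 2) \
                        / (2 * radius_px)
                    d_each = max(0.0, (target_len - cell.length_px) / 2.0)
                _extend(cell, d_each, rng, cfg.bend_sd_rad)

        # user-style division events: split backbones that reached threshold
        if cfg.divisions_enabled and f > 0:
            newborn: list[_Cell] = []
            survivors: list[_Cell] = []
            for cell in cells:
                if cell.length_px < cell.div_len_px:
                    survivors.append(cell)
                    continue
                seg = np.linalg.norm(np.diff(cell.pts, axis=0), axis=1)
                arc = np.concatenate([[0.0], np.cumsum(seg)])
                cut = float(rng.uniform(0.4, 0.6)) * arc[-1]
                k = int(np.searchsorted(arc, cut))
                k = min(max(k, 2), len(cell.pts) - 3)
                for suffix, pts in (("A", cell.pts[:k + 1]),
                                    ("B", cell.pts[k:])):
                    child = _Cell(cell.name + suffix, _resample(pts), f,
                                  div_len_px(),
                                  expr_factor=float(
                                      cell.expr_factor
                                      * rng.normal(1.0, 0.02)),
                                  ch1_factor=float(
                                      cell.ch1_factor
                                      * rng.normal(1.0, 0.02)))
                    newborn.append(child)
                    register(child.name)
                    area0_px2[child.name] = (2 * radius_px * child.length_px
                                             + math.pi * radius_px ** 2)
                lineage.record_division(
                    cell.name, f,
                    PixelMask(frozenset({(0, 0)})),
                    PixelMask(frozenset({(0, 1)})))
            cells = survivors + newborn

        _repel(cells, width_px)

        margin = radius_px + 3
        out_of_canvas = any(
            (c.pts[:, 0].min() < margin or c.pts[:, 1].min() < margin
             or c.pts[:, 0].max() > h - margin
             or c.pts[:, 1].max() > h - margin) for c in cells)
        if out_of_canvas:
            truth.truncated = True
            break

        labels = _rasterize(cells, shape, radius_px, label_of,
                            prev_labels=truth.labels[-1] if truth.labels
                            else None)
        truth.labels.append(labels)

        for pair in _contact_pairs(labels):
            if pair not in contact_visibility:
                contact_visibility[pair] = bool(
                    rng.random() >= cfg.contact_edge_fraction)
        visible = {p for p, v in contact_visibility.items() if v}

        levels1, levels2 = {}, {}
        fold = cfg.induction_fold if f >= cfg.switch_frame else 1.0
        for cell in cells:
            lab = label_of[cell.name]
            lv1 = cfg.baseline_level * fold * cell.expr_factor \
                * cell.ch1_factor
            lv2 = cfg.constitutive_level * cell.expr_factor
            levels1[lab], levels2[lab] = lv1, lv2
            truth.fluor_level[(cell.name, f, "ch1")] = lv1
            truth.fluor_level[(cell.name, f, "ch2")] = lv2
            truth.length_um[(cell.name, f)] = cell.length_px * px
            truth.area_px[(cell.name, f)] = int((labels == lab).sum())

        phase_frames.append(_render_phase(labels, cfg, rng, visible))
        ch1_frames.append(_render_fluor(labels, levels1, cfg, rng))
        ch2_frames.append(_render_fluor(labels, levels2, cfg, rng))

    truth.n_frames = len(phase_frames)
    if truth.n_frames == 0:
        raise ParameterError("colony left the canvas before the first frame")
    times = [i * cfg.dt_min for i in range(truth.n_frames)]
    stacks = {
        "phase": FrameStack("phase", phase_frames, times_min=list(times),
                            pixel_size_um=px),
        "ch1": FrameStack("ch1", ch1_frames, times_min=list(times),
                          pixel_size_um=px),
        "ch2": FrameStack("ch2", ch2_frames, times_min=list(times),
                          pixel_size_um=px),
    }
    # close open truth records at the last simulated frame
    for rec in lineage.cells.values():
        if rec.fate is None:
            rec.end_frame = truth.n_frames - 1
    return stacks, truth


def corrupt(stack: FrameStack, frame: int, mode: str = "blur") -> FrameStack:
    """Return a copy of the stack with one frame degraded.

    ``blur`` emulates an out-of-focus frame (Gaussian blur); ``dark``
    collapses the intensity range.  Useful as a fixture for the
    needs-attention / manual-correction workflow.
    """
    if not 0 <= frame < len(stack):
        raise ParameterError(f"frame {frame} out of range")
    originals = [img.copy() for img in stack.originals]
    images8 = [img.copy() for img in stack.images8]
    if mode == "blur":
        # defocus: strong blur plus loss of camera dynamic range, so the
        # working copy retains almost no local edge structure
        originals[frame] = ndi.gaussian_filter(
            originals[frame].astype(np.float64), 6.0).astype(
                originals[frame].dtype)
        soft = ndi.gaussian_filter(images8[frame].astype(np.float64), 6.0)
        images8[frame] = (np.round(soft / 64.0) * 64.0).astype(np.uint8)
    elif mode == "dark":
        # shutter/illumination failure: the frame collapses to a constant
        originals[frame] = np.zeros_like(originals[frame])
        images8[frame] = np.zeros_like(images8[frame])
    else:
        raise ParameterError(f"unknown corruption mode {mode!r}")
    return FrameStack(stack.channel, originals, images8=images8,
                      times_min=list(stack.times_min),
                      excluded=list(stack.excluded), notes=list(stack.notes),
                      pixel_size_um=stack.pixel_size_um)
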