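"""Translational drift correction between successive frames.

Motorised stages drift: successive frames are displaced by a small whole-
pixel translation that must be undone before tracking.  The estimator scans
all integer shifts up to ``max_shift`` and keeps the one maximising the
normalised cross-correlation (NCC) of the overlapping region; pairwise
shifts between consecutive frames are accumulated and the cumulative shift
is removed from every channel alike.

Only integer translations are modelled; rotation and deformation are out of
scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .stack import FrameStack


@dataclass(frozen=True)
class ShiftVector:
    """Displacement of a moving frame relative to its reference, pixels."""

    dy: int
    dx: int

    def __iter__(self):
        return iter((self.dy, self.dx))

    def __add__(self, other: "ShiftVector") -> "ShiftVector":
        return ShiftVector(self.dy + other.dy, self.dx + other.dx)

    def __neg__(self) -> "ShiftVector":
        return ShiftVector(-self.dy, -self.dx)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shape patches; 0 if either is flat."""
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float((a @ b) / (na * nb))


def estimate_shift(ref: np.ndarray, moving: np.ndarray,
                   max_shift: int) -> ShiftVector:
    """Integer (dy, dx) by which ``moving`` is displaced relative to ``ref``.

    Scans the (2*max_shift+1)^2 candidate shifts and returns the NCC
    maximiser; ties go to the smallest |dy|+|dx|, then smallest dy, then dx.
    """
    if ref.shape != moving.shape:
        raise ParameterError("images must share dimensions")
    if max_shift < 0:
        raise ParameterError("max_shift must be >= 0")
    h, w = ref.shape
    if max_shift >= min(h, w) / 2:
        raise ParameterError(
            f"max_shift {max_shift} too large for {h}x{w} images")
    best: tuple[float, int, int, int, int] | None = None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            # moving content displaced by (dy, dx): moving[r, c] came from
            # ref position (r - dy, c - dx); overlap both accordingly.
            r0, r1 = max(dy, 0), h + min(dy, 0)
            c0, c1 = max(dx, 0), w + min(dx, 0)
            score = _ncc(ref[r0 - dy:r1 - dy, c0 - dx:c1 - dx],
                         moving[r0:r1, c0:c1])
            key = (-score, abs(dy) + abs(dx), dy, dx)
            if best is None or key < best:
                best = key
    assert best is not None
    return ShiftVector(best[2], best[3])


def shift_image(img: np.ndarray, shift: ShiftVector,
                fill=None) -> np.ndarray:
    """Translate an image by (dy, dx), filling vacated pixels.

    ``fill`` defaults to the image's modal value (8-bit background).
    """
    dy, dx = shift
    if fill is None:
        vals, counts = np.unique(img, return_counts=True)
        fill = vals[np.argmax(counts)]
    out = np.full_like(img, fill)
    h, w = img.shape
    r0, r1 = max(dy, 0), h + min(dy, 0)
    c0, c1 = max(dx, 0), w + min(dx, 0)
    if r1 > r0 and c1 > c0:
        out[r0:r1, c0:c1] = img[r0 - dy:r1 - dy, c0 - dx:c1 - dx]
    return out


def register_sequence(stacks: dict[str, FrameStack] | FrameStack,
                      max_shift: int, reference_channel: str = "phase",
                      corr_floor: float = 0.2,
                      ) -> tuple[list[ShiftVector], dict[str, FrameStack]]:
    """Estimate per-frame drift on one channel and undo it on all channels.

    Returns the cumulative shift of every frame relative to frame 0 and the
    registered stacks (working copies and originals both translated).  A
    pairwise correlation peak below ``corr_floor`` raises a warning and
    contributes a zero shift.
    """
    single = isinstance(stacks, FrameStack)
    if single:
        stacks = {stacks.channel: stacks}
    if reference_channel not in stacks:
        reference_channel = next(iter(stacks))
    ref_stack = stacks[reference_channel]
    n = len(ref_stack)
    if n < 2:
        raise ParameterError("need at least 2 frames to register")

    cumulative = [ShiftVector(0, 0)]
    for k in range(1, n):
        sv = estimate_shift(ref_stack.images8[k - 1], ref_stack.images8[k],
                            max_shift)
        dy, dx = sv
        h, w = ref_stack.shape
        r0, r1 = max(dy, 0), h + min(dy, 0)
        c0, c1 = max(dx, 0), w + min(dx, 0)
        peak = _ncc(ref_stack.images8[k - 1][r0 - dy:r1 - dy, c0 - dx:c1 - dx],
                    ref_stack.images8[k][r0:r1, c0:c1])
        if peak < corr_floor:
            warnings.warn(
                f"registration peak {peak:.3f} below floor at frame {k}; "
                "using zero shift", stacklevel=2)
            sv = ShiftVector(0, 0)
        cumulative.append(cumulative[-1] + sv)

    registered: dict[str, FrameStack] = {}
    for name, st in stacks.items():
        orig = [shift_image(img, -cumulative[k])
                for k, img in enumerate(st.originals)]
        img8 = [shift_image(img, -cumulative[k])
                for k, img in enumerate(st.images8)]
        registered[name] = FrameStack(
            channel=st.channel, originals=orig, images8=img8,
            times_min=list(st.times_min), excluded=list(st.excluded),
            notes=list(st.notes), pixel_size_um=st.pixel_size_um)
    if single:
        return cumulative, registered[reference_channel]
    return cumulative, registered
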