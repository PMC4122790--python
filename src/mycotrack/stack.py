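"""Loading and indexing of multi-channel time-lapse image sequences.

A project holds one :class:`FrameStack` per channel: the phase-contrast
channel plus up to three recorded fluorescence channels.  Original images
(any common raster format, any bit depth) are kept for measurement; an 8-bit
working copy is derived for tracking and display.  The 8-bit conversion is a
per-sequence global min-max linear rescale so intensity dynamics across
frames survive in the working copy.

Frames can be excluded (e.g. out-of-focus) without being removed: they stay
in the stack but segmentation and measurement skip them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionMismatchError, FrameMetadataError, ParameterError

CHANNEL_NAMES = ("phase", "ch1", "ch2", "ch3")

_RASTER_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp", ".gif"}


def _frame_key(path: Path) -> tuple[int, str]:
    """Sort key: last integer group in the file name, ties lexicographic."""
    groups = re.findall(r"\d+", path.stem)
    idx = int(groups[-1]) if groups else 0
    return idx, path.name


def to_uint8(images: list[np.ndarray]) -> list[np.ndarray]:
    """Global min-max linear rescale of a sequence to 0..255."""
    mn = min(float(img.min()) for img in images)
    mx = max(float(img.max()) for img in images)
    if mx == mn:
        return [np.zeros_like(img, dtype=np.uint8) for img in images]
    scale = 255.0 / (mx - mn)
    return [np.clip(np.round((img.astype(np.float64) - mn) * scale), 0, 255)
            .astype(np.uint8) for img in images]


@dataclass
class FrameStack:
    """Ordered per-channel image sequence with per-frame metadata."""

    channel: str
    originals: list[np.ndarray]
    images8: list[np.ndarray] = field(default_factory=list)
    times_min: list[float] = field(default_factory=list)
    excluded: list[bool] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __post_init__(self):
        n = len(self.originals)
        if n == 0:
            raise ParameterError("a FrameStack needs at least one frame")
        shapes = {img.shape for img in self.originals}
        if len(shapes) > 1:
            raise DimensionMismatchError(
                f"mixed image dimensions in channel {self.channel!r}: "
                f"{sorted(shapes)}")
        if self.channel not in CHANNEL_NAMES:
            raise ParameterError(
                f"channel must be one of {CHANNEL_NAMES}, got {self.channel!r}")
        if not self.images8:
            self.images8 = to_uint8(self.originals)
        if not self.times_min:
            self.times_min = [float(i) for i in range(n)]
        if not self.excluded:
            self.excluded = [False] * n
        if not self.notes:
            self.notes = [""] * n
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if any(t2 <= t1 for t1, t2 in zip(self.times_min, self.times_min[1:])):
            raise FrameMetadataError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.originals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.originals[0].shape

    def active_frames(self) -> list[int]:
        """Indices of frames not flagged as excluded."""
        return [i for i, ex in enumerate(self.excluded) if not ex]


def load_sequence(directory, channel: str, pixel_size_um: float = 1.0,
                  dt_min: float | None = None,
                  times_min: list[float] | None = None) -> FrameStack:
    """Load a folder of raster images into a FrameStack.

    Frames are ordered by the last integer group in each file name (ties
    broken lexicographically).  ``dt_min`` assigns uniform times
    ``0, dt, 2*dt, ...``; ``times_min`` assigns explicit per-frame times.
    """
    directory = Path(directory)
    paths = sorted((p for p in directory.iterdir()
                    if p.suffix.lower() in _RASTER_SUFFIXES), key=_frame_key)
    if not paths:
        raise ParameterError(f"no raster images found in {directory}")
    import imageio.v3 as iio

    originals: list[np.ndarray] = []
    for p in paths:
        try:
            img = np.asarray(iio.imread(p))
        except Exception as exc:  # noqa: BLE001 - re-raise with file name
            raise OSError(f"unreadable image file {p}: {exc}") from exc
        if img.ndim == 3:  # collapse RGB(A) to first plane
            img = img[..., 0]
        originals.append(img)
    shapes = {img.shape for img in originals}
    if len(shapes) > 1:
        bad = [str(p) for p, img in zip(paths, originals)
               if img.shape != originals[0].shape]
        raise DimensionMismatchError(
            f"images with differing dimensions: {bad}")
    if times_min is None:
        step = 1.0 if dt_min is None else float(dt_min)
        times_min = [i * step for i in range(len(originals))]
    return FrameStack(channel=channel, originals=originals,
                      times_min=list(times_min), pixel_size_um=pixel_size_um)


def set_frame_metadata(stack: FrameStack, frame_index: int,
                       time_min: float | None = None,
                       excluded: bool | None = None,
                       note: str | None = None) -> FrameStack:
    """Update one frame's metadata in place (and return the stack).

    Exclusion is non-destructive: the frame's images are untouched and it
    returns to processing when the flag is cleared.
    """
    if not 0 <= frame_index < len(stack):
        raise FrameMetadataError(
            f"frame index {frame_index} out of range 0..{len(stack) - 1}")
    if time_min is not None:
        t = float(time_min)
        if frame_index > 0 and t <= stack.times_min[frame_index - 1]:
            raise FrameMetadataError("frame times must be strictly increasing")
        if (frame_index + 1 < len(stack)
                and t >= stack.times_min[frame_index + 1]):
            raise FrameMetadataError("frame times must be strictly increasing")
        stack.times_min[frame_index] = t
    if excluded is not None:
        stack.excluded[frame_index] = bool(excluded)
    if note is not None:
        stack.notes[frame_index] = str(note)
    return stack


def save_working_copies(stack: FrameStack, directory) -> list[Path]:
    """Write the 8-bit working copies as a PNG sequence."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    width = max(4, len(str(len(stack) - 1)))
    for i, img in enumerate(stack.images8):
        p = directory / f"{stack.channel}_{i:0{width}d}.png"
        iio.imwrite(p, img)
        out.append(p)
    return out
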