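"""Pixel-set regions of interest (ROIs) and their serialised forms.

A cell's selection in one frame is a :class:`PixelMask`: a set of in-bounds
``(row, col)`` coordinates, 0-based with origin at the top-left corner.  The
same convention is used everywhere, including the datastore.  Masks are
persisted as row-wise run-length-encoded (RLE) text, which is compact and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Coord = tuple[int, int]


@dataclass(frozen=True)
class PixelMask:
    """Set of pixels belonging to one cell in one frame."""

    pixels: frozenset[Coord]
    frame_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pixels", frozenset(
            (int(r), int(c)) for r, c in self.pixels))

    @property
    def area(self) -> int:
        return len(self.pixels)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.pixels)

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(rmin, cmin, rmax, cmax), inclusive."""
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return min(rows), min(cols), max(rows), max(cols)

    def to_array(self, shape: tuple[int, int]) -> np.ndarray:
        """Render as a boolean image of the given ``(height, width)``."""
        out = np.zeros(shape, dtype=bool)
        if self.pixels:
            rr, cc = zip(*self.pixels)
            out[np.asarray(rr), np.asarray(cc)] = True
        return out

    @classmethod
    def from_array(cls, arr: np.ndarray, frame_index: int = 0) -> "PixelMask":
        rr, cc = np.nonzero(arr)
        return cls(frozenset(zip(rr.tolist(), cc.tolist())), frame_index)

    def intersects(self, other: "PixelMask") -> bool:
        return not self.pixels.isdisjoint(other.pixels)


def mask_to_rle(mask: PixelMask) -> str:
    """Row-wise RLE: ``r:c+len,c+len;r:...`` with rows and runs sorted."""
    by_row: dict[int, list[int]] = {}
    for r, c in mask.pixels:
        by_row.setdefault(r, []).append(c)
    parts = []
    for r in sorted(by_row):
        cols = sorted(by_row[r])
        runs = []
        start = prev = cols[0]
        for c in cols[1:]:
            if c == prev + 1:
                prev = c
            else:
                runs.append(f"{start}+{prev - start + 1}")
                start = prev = c
        runs.append(f"{start}+{prev - start + 1}")
        parts.append(f"{r}:" + ",".join(runs))
    return ";".join(parts)


def rle_to_mask(rle: str, frame_index: int = 0) -> PixelMask:
    pixels: set[Coord] = set()
    if rle:
        for part in rle.split(";"):
            row_s, runs = part.split(":")
            r = int(row_s)
            for run in runs.split(","):
                start_s, len_s = run.split("+")
                start, n = int(start_s), int(len_s)
                pixels.update((r, c) for c in range(start, start + n))
    return PixelMask(frozenset(pixels), frame_index)


def polygon_to_mask(vertices: list[Coord], shape: tuple[int, int],
                    frame_index: int = 0) -> PixelMask:
    """Rasterise a closed polygon given as (row, col) vertices."""
    from skimage.draw import polygon as sk_polygon

    rr = np.asarray([v[0] for v in vertices], dtype=float)
    cc = np.asarray([v[1] for v in vertices], dtype=float)
    pr, pc = sk_polygon(rr, cc, shape=shape)
    return PixelMask(frozenset(zip(pr.tolist(), pc.tolist())), frame_index)


def load_polygon_file(path, shape: tuple[int, int],
                      frame_index: int = 0) -> PixelMask:
    """Read a polygon text file: one ``row col`` pair per line."""
    verts: list[Coord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            r, c = line.replace(",", " ").split()[:2]
            verts.append((int(round(float(r))), int(round(float(c)))))
    return polygon_to_mask(verts, shape, frame_index)


def load_labeled_mask_png(path, frame_index: int = 0) -> dict[int, PixelMask]:
    """Read a labelled-mask image; returns {label: mask} for labels > 0."""
    import imageio.v3 as iio

    lab = np.asarray(iio.imread(path))
    if lab.ndim == 3:
        lab = lab[..., 0]
    out: dict[int, PixelMask] = {}
    for value in np.unique(lab):
        if value == 0:
            continue
        out[int(value)] = PixelMask.from_array(lab == value, frame_index)
    return out


@dataclass
class MaskSet:
    """Ordered (by cell name) collection of masks for one frame."""

    masks: dict[str, PixelMask] = field(default_factory=dict)

    def ordered(self) -> list[tuple[str, PixelMask]]:
        return sorted(self.masks.items())
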