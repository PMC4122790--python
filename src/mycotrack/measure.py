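"""Per-cell, per-frame, per-channel intensity and geometry measurements.

Measurements are always taken on the *original* images (full bit depth);
the 8-bit working copies only ever drive tracking.  A selection can be
eroded before measuring to suppress edge pixels of uncertain ownership, and
a user-defined cell-free background region yields per-frame, per-channel
background means that are subtracted to give ``mean_corrected`` values.

Derived per-cell variables follow the same skeleton machinery as the
tracker: length is the skeleton pixel count times the pixel size (accurate
to about +-w near the poles), and two growth rates are reported — a linear
elongation rate (um/h, least-squares slope of length vs time) and an
exponential area rate (1/h, slope of ln(area) vs time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import MeasurementError, NotDefinedError
from .masks import PixelMask
from .segmentation import _disk_offsets, thin


@dataclass(frozen=True)
class MeasureConfig:
    channels: tuple[str, ...] = ("ch1", "ch2")
    erode_px: int = 0
    variables: tuple[str, ...] = ("mean", "sd", "min", "max", "integrated")


def erode_mask(mask: PixelMask, erode_px: int,
               shape: tuple[int, int]) -> PixelMask:
    """Morphological erosion with a Euclidean disk of radius ``erode_px``."""
    if erode_px == 0:
        return mask
    arr = mask.to_array(shape)
    r = erode_px
    fp = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
    for dr, dc in _disk_offsets(r):
        fp[dr + r, dc + r] = True
    eroded = ndi.binary_erosion(arr, structure=fp)
    if not eroded.any():
        raise MeasurementError(
            f"mask empty after erosion by {erode_px} px")
    return PixelMask.from_array(eroded, mask.frame_index)


def measure_roi(mask: PixelMask, img: np.ndarray,
                erode_px: int = 0) -> dict[str, float]:
    """Intensity statistics of one selection on one original image."""
    if mask.area == 0:
        raise MeasurementError("cannot measure an empty mask")
    use = erode_mask(mask, erode_px, img.shape)
    rr, cc = zip(*use.pixels)
    vals = img[np.asarray(rr), np.asarray(cc)].astype(np.float64)
    mean = float(vals.mean())
    return {
        "area_px": float(use.area),
        "mean": mean,
        "sd": float(vals.std()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "integrated": mean * use.area,
    }


def mask_length_um(mask: PixelMask, shape: tuple[int, int],
                   pixel_size_um: float) -> float:
    """Cell length: skeleton pixel count x pixel size."""
    return float(thin(mask.to_array(shape)).sum()) * pixel_size_um


def measure_background(bg_mask: PixelMask, images: list[np.ndarray],
                       frames: list[int]) -> dict[int, float]:
    """Mean over the background region of each listed frame's image."""
    if bg_mask.area == 0:
        raise MeasurementError("background mask must be nonempty")
    rr, cc = zip(*bg_mask.pixels)
    rr, cc = np.asarray(rr), np.asarray(cc)
    return {f: float(images[f][rr, cc].mean()) for f in frames}


def linear_rate(times_min: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope of values vs time, per hour."""
    if len(times_min) < 2:
        raise NotDefinedError("need >= 2 points for a rate")
    slope = np.polyfit(np.asarray(times_min, dtype=float) / 60.0,
                       np.asarray(values, dtype=float), 1)[0]
    return float(slope)


def exponential_rate(times_min: np.ndarray, values: np.ndarray) -> float:
    """Slope of ln(values) vs time, per hour."""
    vals = np.asarray(values, dtype=float)
    if np.any(vals <= 0):
        raise NotDefinedError("exponential rate needs positive values")
    return linear_rate(times_min, np.log(vals))


def ratio_stats(num: dict[tuple[str, int], float],
                den: dict[tuple[str, int], float]
                ) -> dict[int, tuple[float, float, int, int]]:
    """Across-cell per-frame mean/SD of per-cell ratios.

    ``num`` and ``den`` map (cell, frame) to background-corrected means.
    Cells whose denominator is <= 0 at a frame are excluded there; the
    exclusion count is reported.  Returns
    {frame: (mean, sd, n_used, n_excluded)}.
    """
    by_frame: dict[int, list[float]] = {}
    excluded: dict[int, int] = {}
    for (cell, frame), g in num.items():
        r = den.get((cell, frame))
        if r is None:
            continue
        if r <= 0:
            excluded[frame] = excluded.get(frame, 0) + 1
            continue
        by_frame.setdefault(frame, []).append(g / r)
    out = {}
    for frame in sorted(by_frame):
        vals = np.asarray(by_frame[frame])
        out[frame] = (float(vals.mean()), float(vals.std()), len(vals),
                      excluded.get(frame, 0))
    return out
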