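"""Skeleton-guided segmentation and tracking of mycobacteria-like cells.

The tracker assumes worm-shaped cells of roughly fixed width that change
only slightly between frames and grow almost exclusively at their poles.
Each frame is processed as follows:

1. a 3x3 Sobel gradient magnitude of the frame is computed;
2. the gradient is auto-thresholded (IsoData by default) into binary edges;
3. the binary edges are thinned (Zhang-Suen) into a one-pixel edge map;
4. each cell's previous-frame selection is thinned to its skeleton;
5. the skeleton is grown into the "adjusted area": pixels that fit within
   the configured distance ``w`` (cell half-width) of a detected edge and
   lie near the previous skeleton — this re-centres the selection;
6. the (re-thinned) adjusted skeleton is extended lengthwise at its poles
   by probing half-disc areas of radius ``p`` oriented away from the cell,
   subject to the maximal area increase ``a``;
7. the new selection is reconstructed by smearing a disk of radius ``w``
   along the adjusted skeleton and the admitted pole pixels.

Cells are processed round-robin in alphabetical order within a frame;
pixels claimed by an earlier cell are unavailable to later cells, which
makes the (stated) order dependence explicit.  Division is never inferred
automatically — it is annotated by the user (see :mod:`mycotrack.lineage`).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import CellLostError, DegenerateHistogramError, ParameterError
from .masks import Coord, PixelMask

THRESHOLD_METHODS = ("isodata", "otsu", "mean", "triangle", "li", "yen")


@dataclass(frozen=True)
class SegParams:
    """The three tracking parameters, all in pixels.

    ``cell_width`` is the disk *radius* used both for the edge-distance test
    and for reconstruction (so the reconstructed tube is ~2w+1 wide);
    ``max_pole_elongation`` is the radius of the half-disc probed beyond
    each pole; ``max_area_increase`` caps the pixel-count growth of a
    selection between consecutive frames.
    """

    cell_width: int = 3
    max_pole_elongation: int = 10
    max_area_increase: int = 35
    direction_steps: int = 5  # skeleton steps used to estimate pole direction

    def __post_init__(self):
        if self.cell_width < 1:
            raise ParameterError("cell_width must be >= 1")
        if self.max_pole_elongation < 0 or self.max_area_increase < 0:
            raise ParameterError("pole elongation and area increase are >= 0")


# ---------------------------------------------------------------------------
# Edge map construction
# ---------------------------------------------------------------------------

def _sobel_pair(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = img.astype(np.float64)
    P = np.pad(f, 1, mode="edge")
    nw, n, ne = P[:-2, :-2], P[:-2, 1:-1], P[:-2, 2:]
    w_, e = P[1:-1, :-2], P[1:-1, 2:]
    sw, s, se = P[2:, :-2], P[2:, 1:-1], P[2:, 2:]
    gx = (ne + 2 * e + se) - (nw + 2 * w_ + sw)
    gy = (sw + 2 * s + se) - (nw + 2 * n + ne)
    return gx, gy


def edge_magnitude(img: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude, rescaled linearly to 0..255 (uint8).

    Borders are handled by edge replication, so a flat field stays flat.
    """
    gx, gy = _sobel_pair(img)
    mag = np.hypot(gx, gy)
    top = mag.max()
    if top == 0:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round(mag * (255.0 / top)).astype(np.uint8)


def isodata_threshold(img: np.ndarray) -> int:
    """Iterative intermeans (IsoData) threshold of an 8-bit image.

    Returns the fixed point of ``t = floor((mean(v <= t) + mean(v > t))/2)``
    starting from the midpoint of the occupied histogram range.
    """
    img = np.asarray(img)
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256)[:256]
    occupied = np.nonzero(hist)[0]
    if occupied.size < 2:
        raise DegenerateHistogramError(
            "cannot threshold a single-valued image")
    lo, hi = int(occupied[0]), int(occupied[-1])
    values = np.arange(256, dtype=np.float64)
    csum = np.cumsum(hist)                    # counts of v <= t
    cmass = np.cumsum(hist * values)          # intensity mass of v <= t
    total_n, total_m = csum[-1], cmass[-1]

    t = (lo + hi) // 2
    seen: set[int] = set()
    while t not in seen:
        seen.add(t)
        n0, m0 = csum[t], cmass[t]
        n1, m1 = total_n - n0, total_m - m0
        if n0 == 0 or n1 == 0:  # pragma: no cover - unreachable for lo<t<hi
            break
        t = int((m0 / n0 + m1 / n1) // 2)
    return t


def auto_threshold(img: np.ndarray, method: str = "isodata") -> np.ndarray:
    """Binarise a gradient image: True where value exceeds the threshold."""
    if method not in THRESHOLD_METHODS:
        raise ParameterError(
            f"method must be one of {THRESHOLD_METHODS}, got {method!r}")
    img = np.asarray(img)
    if np.unique(img).size < 2:
        raise DegenerateHistogramError(
            "cannot threshold a single-valued image")
    if method == "isodata":
        t = isodata_threshold(img)
    else:
        from skimage import filters

        fn = {"otsu": filters.threshold_otsu,
              "mean": filters.threshold_mean,
              "triangle": filters.threshold_triangle,
              "li": filters.threshold_li,
              "yen": filters.threshold_yen}[method]
        t = fn(img)
    return img > t


def threshold_gallery(img: np.ndarray
                      ) -> list[tuple[str, np.ndarray | None]]:
    """One binarisation per supported method, for side-by-side comparison.

    A method that fails (degenerate histogram) contributes a ``None`` entry
    instead of aborting the gallery.
    """
    out: list[tuple[str, np.ndarray | None]] = []
    for method in THRESHOLD_METHODS:
        try:
            out.append((method, auto_threshold(img, method)))
        except DegenerateHistogramError:
            out.append((method, None))
    return out


# ---------------------------------------------------------------------------
# Zhang-Suen thinning
# ---------------------------------------------------------------------------

def thin(binary: np.ndarray) -> np.ndarray:
    """Two-subiteration (Zhang-Suen) thinning to a one-pixel-wide skeleton.

    Both deletion passes are parallel: conditions are evaluated on a
    snapshot of the image and all flagged pixels are removed at once.
    Iterates until neither subiteration deletes a pixel.
    """
    img = np.ascontiguousarray(binary, dtype=bool).copy()
    if not img.any():
        return img
    changed = True
    while changed:
        changed = False
        for sub in (0, 1):
            P = np.pad(img, 1)
            p2 = P[:-2, 1:-1]
            p3 = P[:-2, 2:]
            p4 = P[1:-1, 2:]
            p5 = P[2:, 2:]
            p6 = P[2:, 1:-1]
            p7 = P[2:, :-2]
            p8 = P[1:-1, :-2]
            p9 = P[:-2, :-2]
            ring = (p2, p3, p4, p5, p6, p7, p8, p9)
            B = np.zeros(img.shape, dtype=np.uint8)
            for n in ring:
                B += n
            A = np.zeros(img.shape, dtype=np.uint8)
            for i in range(8):
                A += (~ring[i]) & ring[(i + 1) % 8]
            if sub == 0:
                c1 = ~(p2 & p4 & p6)
                c2 = ~(p4 & p6 & p8)
            else:
                c1 = ~(p2 & p4 & p8)
                c2 = ~(p2 & p6 & p8)
            delete = img & (B >= 2) & (B <= 6) & (A == 1) & c1 & c2
            if delete.any():
                img &= ~delete
                changed = True
    return img


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class Skeleton:
    """One-pixel-wide medial curve; endpoints are derived, not stored."""

    pixels: frozenset[Coord]

    @property
    def endpoints(self) -> frozenset[Coord]:
        """Skeleton pixels with at most one skeleton 8-neighbour.

        An isolated single-pixel skeleton counts as an endpoint (two
        coincident poles of a degenerate cell).
        """
        out = set()
        for r, c in self.pixels:
            k = sum((r + dr, c + dc) in self.pixels for dr, dc in _N8)
            if k <= 1:
                out.add((r, c))
        return frozenset(out)


def skeletonize_mask(mask: PixelMask, shape: tuple[int, int]) -> Skeleton:
    """Thin a cell mask to its skeleton."""
    arr = thin(mask.to_array(shape))
    if not arr.any():
        raise CellLostError(reason="mask thinned to the empty set")
    rr, cc = np.nonzero(arr)
    return Skeleton(frozenset(zip(rr.tolist(), cc.tolist())))


def _pole_direction(pixels: frozenset[Coord], endpoint: Coord,
                    k: int) -> tuple[float, float] | None:
    """Unit vector pointing outward at a pole.

    Walks ``k`` steps inward from the endpoint along the skeleton (BFS graph
    distance); the direction is from that inner pixel to the endpoint.
    Endpoints closer than ``k`` steps to a branch/end use the farthest
    reachable pixel.  Returns ``None`` for a degenerate (single-pixel)
    skeleton with no inward direction.
    """
    dist = {endpoint: 0}
    queue = deque([endpoint])
    farthest = endpoint
    while queue:
        cur = queue.popleft()
        if dist[cur] >= k:
            farthest = cur
            break
        for dr, dc in _N8:
            nxt = (cur[0] + dr, cur[1] + dc)
            if nxt in pixels and nxt not in dist:
                dist[nxt] = dist[cur] + 1
                if dist[nxt] > dist[farthest]:
                    farthest = nxt
                queue.append(nxt)
    if farthest == endpoint:
        return None
    vy = endpoint[0] - farthest[0]
    vx = endpoint[1] - farthest[1]
    norm = float(np.hypot(vy, vx))
    return (vy / norm, vx / norm)


# ---------------------------------------------------------------------------
# Selection propagation steps
# ---------------------------------------------------------------------------

def _disk_offsets(radius: int) -> list[Coord]:
    out = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr * dr + dc * dc <= radius * radius:
                out.append((dr, dc))
    return out


def _dilate_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological dilation with a Euclidean disk of the given radius."""
    if radius == 0:
        return mask.copy()
    fp = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=bool)
    for dr, dc in _disk_offsets(radius):
        fp[dr + radius, dc + radius] = True
    return ndi.binary_dilation(mask, structure=fp)


def _render(pixels, shape) -> np.ndarray:
    arr = np.zeros(shape, dtype=bool)
    if pixels:
        rr, cc = zip(*pixels)
        arr[np.asarray(rr), np.asarray(cc)] = True
    return arr


def edge_distance(edges: np.ndarray) -> np.ndarray:
    """Euclidean distance of every pixel to the nearest edge pixel."""
    if not edges.any():
        return np.full(edges.shape, np.inf)
    return ndi.distance_transform_edt(~edges)


def adjust_skeleton_area(skel: Skeleton, edges: np.ndarray, w: int,
                         dist: np.ndarray | None = None,
                         claimed: np.ndarray | None = None
                         ) -> frozenset[Coord]:
    """Grow the previous skeleton into the area that fits the current edges.

    A pixel is admitted iff it lies within ``w`` whole pixel steps of the
    nearest detected edge (Euclidean distance < w+1, i.e. the distance
    rounded down to whole pixels is <= w) and within ``w`` of some
    seed-skeleton pixel.  Growth
    is 4-connected with edge pixels acting as barriers, so the selection
    cannot leak across a detected contour; this re-centres a skeleton that
    drifted off the cell midline.
    """
    if w < 1:
        raise ParameterError("w must be >= 1")
    if not edges.any():
        raise CellLostError(reason="no edges detected anywhere in the frame")
    if dist is None:
        dist = edge_distance(edges)
    shape = edges.shape
    skel_mask = _render(skel.pixels, shape)
    near_skel = ndi.distance_transform_edt(~skel_mask) <= w
    allowed = (dist <= w + 1) & ~edges & near_skel
    if claimed is not None:
        allowed &= ~claimed
    seeds = skel_mask & allowed
    if not seeds.any():
        raise CellLostError(
            reason="no skeleton pixel fits within the configured distance "
                   "from the cell edge")
    labels, _ = ndi.label(allowed, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    keep = np.unique(labels[seeds])
    grown = np.isin(labels, keep[keep > 0])
    rr, cc = np.nonzero(grown)
    return frozenset(zip(rr.tolist(), cc.tolist()))


def elongate_poles(guide: Skeleton, edges: np.ndarray, params: SegParams,
                   prev_area: int, dist: np.ndarray | None = None,
                   claimed: np.ndarray | None = None) -> frozenset[Coord]:
    """Admit pole-elongation pixels beyond each skeleton endpoint.

    Probes the half-disc of radius ``p`` oriented away from the cell at
    every endpoint; candidates must pass the same edge-distance test as the
    body (<= ``w``) and are admitted nearest-first until the projected
    reconstructed area would exceed ``prev_area + a``.  An empty result is
    valid (a non-growing pole).
    """
    w, p, a = (params.cell_width, params.max_pole_elongation,
               params.max_area_increase)
    if prev_area <= 0:
        raise ParameterError("prev_area must be > 0")
    if dist is None:
        dist = edge_distance(edges)
    shape = edges.shape
    cap = prev_area + a
    guide_mask = _render(guide.pixels, shape)
    # project the *clipped* reconstruction: segment_frame keeps only the
    # edge-bounded region(s) around the cell body, so the area budget must
    # count the same pixels — not the dilation spill beyond the contour
    open_lab, _ = ndi.label(~edges, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    body_labels = np.unique(open_lab[guide_mask])
    in_region = np.isin(open_lab, body_labels[body_labels > 0]) \
        & (dist <= w + 1)
    covered = _dilate_disk(guide_mask, w) & in_region
    if claimed is not None:
        covered &= ~claimed
    area = int(covered.sum())
    disk = _disk_offsets(w)
    admitted: set[Coord] = set()

    edge_arr = edges

    def allowed(q: Coord, e: Coord,
                direction: tuple[float, float] | None) -> bool:
        dr, dc = q[0] - e[0], q[1] - e[1]
        d2 = dr * dr + dc * dc
        if d2 == 0 or d2 > p * p:
            return False
        if direction is not None and (
                dr * direction[0] + dc * direction[1]) <= 0:
            return False
        if not (0 <= q[0] < shape[0] and 0 <= q[1] < shape[1]):
            return False
        if edge_arr[q] or dist[q] > w + 1:
            return False
        if claimed is not None and claimed[q]:
            return False
        return not guide_mask[q]

    import heapq

    for endpoint in sorted(guide.endpoints):
        direction = _pole_direction(guide.pixels, endpoint,
                                    params.direction_steps)
        # nearest-first flood from the endpoint; detected edges block the
        # probe, so admission stops at the cell's current contour instead
        # of running past the pole into the background
        seen = {endpoint}
        heap: list[tuple[int, Coord]] = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            q = (endpoint[0] + dr, endpoint[1] + dc)
            if q not in seen and q not in admitted \
                    and allowed(q, endpoint, direction):
                seen.add(q)
                heapq.heappush(heap, (dr * dr + dc * dc, q))
        capped = False
        while heap and not capped:
            _, q = heapq.heappop(heap)
            gain = 0
            fresh = []
            for dr, dc in disk:
                rr, cc = q[0] + dr, q[1] + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1] \
                        and not covered[rr, cc] and in_region[rr, cc] \
                        and (claimed is None or not claimed[rr, cc]):
                    gain += 1
                    fresh.append((rr, cc))
            if area + gain > cap:
                capped = True
                break
            admitted.add(q)
            area += gain
            for rr, cc in fresh:
                covered[rr, cc] = True
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nq = (q[0] + dr, q[1] + dc)
                if nq not in seen and nq not in admitted \
                        and allowed(nq, endpoint, direction):
                    seen.add(nq)
                    d2 = ((nq[0] - endpoint[0]) ** 2
                          + (nq[1] - endpoint[1]) ** 2)
                    heapq.heappush(heap, (d2, nq))
    return frozenset(admitted)


def reconstruct(guide, w: int, shape: tuple[int, int],
                frame_index: int = 0,
                claimed: np.ndarray | None = None) -> PixelMask:
    """Smear a disk of radius ``w`` along the guide pixels.

    Every output pixel is within ``w`` of a guide pixel and every guide
    pixel is inside the output.  The result is clipped to the image bounds
    and only the largest 8-connected component is retained (stray fragments
    are dropped).
    """
    pixels = guide.pixels if isinstance(guide, Skeleton) else frozenset(guide)
    if not pixels:
        raise ParameterError("guide must be nonempty")
    mask = _dilate_disk(_render(pixels, shape), w)
    if claimed is not None:
        mask &= ~claimed
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return PixelMask.from_array(mask, frame_index)


def _trim_to_cap(mask: np.ndarray, guide_mask: np.ndarray,
                 cap: int) -> np.ndarray:
    """Drop reconstructed pixels farthest from the guide until <= cap."""
    excess = int(mask.sum()) - cap
    if excess <= 0:
        return mask
    dist = ndi.distance_transform_edt(~guide_mask)
    rr, cc = np.nonzero(mask)
    order = sorted(zip(dist[rr, cc].tolist(), rr.tolist(), cc.tolist()),
                   reverse=True)
    out = mask.copy()
    for _, r, c in order[:excess]:
        out[r, c] = False
    return out


def build_edge_map(img: np.ndarray, method: str = "isodata") -> np.ndarray:
    """Frame edge map: Sobel magnitude -> auto-threshold -> thinning."""
    return thin(auto_threshold(edge_magnitude(img), method))


def segment_frame(prev_masks: list[tuple[str, PixelMask]],
                  frame_img: np.ndarray, params: SegParams,
                  method: str = "isodata", frame_index: int = 0,
                  edge_map: np.ndarray | None = None,
                  fixed_masks: list[tuple[str, PixelMask]] | None = None,
                  ) -> tuple[list[tuple[str, PixelMask]],
                             dict[str, CellLostError]]:
    """Propagate every cell's previous selection into the current frame.

    The edge map is built once and shared; cells are processed round-robin
    in alphabetical order, earlier cells claiming contested pixels first.
    ``fixed_masks`` are selections already fixed on this frame (manual
    seeds, e.g. freshly annotated daughters): their pixels are claimed up
    front.  Per-cell failures are collected (not raised) and the remaining
    cells are still processed.
    """
    shape = frame_img.shape
    edges = build_edge_map(frame_img, method) if edge_map is None else edge_map
    dist = edge_distance(edges)
    claimed = np.zeros(shape, dtype=bool)
    for _, fixed in (fixed_masks or []):
        claimed |= fixed.to_array(shape)
    # joint areas are assigned once and retained: a cell may not expand into
    # pixels the previous frame assigned to a neighbour, even where no edge
    # separates them (the neighbour re-claims or vacates them on its own turn)
    prev_union = np.zeros(shape, dtype=bool)
    prev_arrs: dict[str, np.ndarray] = {}
    for name, prev in prev_masks:
        prev_arrs[name] = prev.to_array(shape)
        prev_union |= prev_arrs[name]
    results: list[tuple[str, PixelMask]] = []
    failures: dict[str, CellLostError] = {}
    for name, prev in sorted(prev_masks):
        try:
            if prev.area == 0:
                raise CellLostError(reason="empty previous mask")
            blocked = claimed | (prev_union & ~prev_arrs[name])
            skel = skeletonize_mask(prev, shape)
            adjusted = adjust_skeleton_area(skel, edges, params.cell_width,
                                            dist=dist, claimed=blocked)
            guide_arr = thin(_render(adjusted, shape))
            if not guide_arr.any():
                raise CellLostError(reason="adjusted area thinned to nothing")
            rr, cc = np.nonzero(guide_arr)
            guide = Skeleton(frozenset(zip(rr.tolist(), cc.tolist())))
            poles = elongate_poles(guide, edges, params, prev.area,
                                   dist=dist, claimed=blocked)
            full_guide = guide.pixels | poles
            new = reconstruct(full_guide, params.cell_width, shape,
                              frame_index=frame_index, claimed=blocked)
            # the smeared disk spills across the detected contour; keep the
            # edge-bounded region(s) around the cell-body skeleton, so the
            # selection ends at the cell edge like every other step
            arr = new.to_array(shape) & ~edges
            lab4, _ = ndi.label(arr, structure=np.array(
                [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
            body = lab4[guide_arr]
            keep = np.unique(body[body > 0])
            if keep.size == 0:
                raise CellLostError(
                    reason="reconstruction separated from the skeleton")
            arr = np.isin(lab4, keep)
            arr = _trim_to_cap(arr, _render(full_guide, shape),
                               prev.area + params.max_area_increase)
            if not arr.any():
                raise CellLostError(reason="selection vanished after trimming")
            claimed |= arr
            results.append((name, PixelMask.from_array(arr, frame_index)))
        except CellLostError as exc:
            failures[name] = CellLostError(cell=name, frame=frame_index,
                                           reason=exc.reason or str(exc))
    return results, failures
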