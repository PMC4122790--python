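"""Unit tests for the edge map, thresholding, thinning and the
skeleton-guided propagation steps."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from mycotrack.benchmark import (euclidean_disk_reference, isodata_reference,
                                 random_blob, zhang_suen_reference)
from mycotrack.errors import (CellLostError, DegenerateHistogramError,
                              ParameterError)
from mycotrack.masks import PixelMask
from mycotrack.segmentation import (SegParams, Skeleton, adjust_skeleton_area,
                                    auto_threshold, edge_distance,
                                    edge_magnitude, elongate_poles,
                                    isodata_threshold, reconstruct,
                                    segment_frame, skeletonize_mask, thin,
                                    threshold_gallery)


# ---------------------------------------------------------------------------
# Sobel gradient
# ---------------------------------------------------------------------------

class TestEdgeMagnitude:
    def test_flat_field_has_zero_gradient(self):
        assert not edge_magnitude(np.full((16, 16), 77, np.uint8)).any()

    def test_vertical_step_matches_direct_convolution(self):
        # |Gx| = 4 * step on the two columns adjacent to a vertical step
        img = np.zeros((10, 12), dtype=np.uint8)
        img[:, 6:] = 8
        from mycotrack.segmentation import _sobel_pair

        gx, gy = _sobel_pair(img)
        kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
        ref_gx = ndi.convolve(img.astype(float), kx[::-1, ::-1],
                              mode="nearest")
        assert np.allclose(gx, ref_gx)
        assert np.all(np.abs(gx[:, 5]) == 32)
        assert np.all(np.abs(gx[:, 6]) == 32)
        assert not gy[2:-2].any()

    def test_transpose_symmetry(self, rng):
        img = rng.integers(0, 256, size=(20, 31)).astype(np.uint8)
        assert np.array_equal(edge_magnitude(img.T), edge_magnitude(img).T)


# ---------------------------------------------------------------------------
# IsoData thresholding
# ---------------------------------------------------------------------------

class TestIsodata:
    def test_two_population_midpoint(self):
        img = np.array([[10] * 8 + [20] * 8] * 4, dtype=np.uint8)
        assert isodata_threshold(img) == 15
        binary = auto_threshold(img)
        assert np.array_equal(binary, img == 20)

    def test_extreme_bimodal(self):
        img = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        assert isodata_threshold(img) == 127

    def test_single_valued_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            isodata_threshold(np.full((8, 8), 3, np.uint8))
        with pytest.raises(DegenerateHistogramError):
            auto_threshold(np.full((8, 8), 3, np.uint8), "otsu")

    def test_fixed_point_on_random_histograms(self, rng):
        # the returned threshold must be one of the exhaustive-scan fixed
        # points of the intermeans equation
        for _ in range(25):
            vals = rng.integers(0, 256, size=500).astype(np.uint8)
            if np.unique(vals).size < 2:
                continue
            t = isodata_threshold(vals.reshape(20, 25))
            assert t in isodata_reference(vals)


class TestThresholdGallery:
    def test_gallery_order_and_separation(self):
        img = np.array([[10] * 8 + [20] * 8] * 4, dtype=np.uint8)
        gallery = threshold_gallery(img)
        assert [name for name, _ in gallery] == [
            "isodata", "otsu", "mean", "triangle", "li", "yen"]
        for name, binary in gallery:
            assert binary is not None, name
            # every method separates the two populations
            assert np.array_equal(binary, img == 20) \
                or np.array_equal(binary, img >= 10), name

    def test_gallery_survives_degenerate_image(self):
        gallery = threshold_gallery(np.full((8, 8), 5, np.uint8))
        assert len(gallery) == 6
        assert all(binary is None for _, binary in gallery)

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            auto_threshold(np.zeros((4, 4), np.uint8), "magic")


# ---------------------------------------------------------------------------
# Zhang-Suen thinning
# ---------------------------------------------------------------------------

class TestThinning:
    def test_thin_line_is_unchanged(self):
        img = np.zeros((9, 20), dtype=bool)
        img[4, 2:18] = True
        assert np.array_equal(thin(img), img)

    def test_filled_square_matches_reference_rules(self):
        img = np.zeros((9, 9), dtype=bool)
        img[2:7, 2:7] = True
        assert np.array_equal(thin(img), zhang_suen_reference(img))

    def test_disjoint_blobs_stay_disjoint(self):
        img = np.zeros((20, 20), dtype=bool)
        img[2:7, 2:7] = True
        img[12:18, 10:18] = True
        out = thin(img)
        _, n = ndi.label(out, structure=np.ones((3, 3)))
        assert n == 2

    def test_matches_reference_on_random_blobs(self, rng):
        for _ in range(20):
            blob = random_blob(rng)
            assert np.array_equal(thin(blob), zhang_suen_reference(blob))

    def test_preserves_component_count(self, rng):
        eight = np.ones((3, 3))
        for _ in range(10):
            blob = random_blob(rng)
            _, n_in = ndi.label(blob, structure=eight)
            _, n_out = ndi.label(thin(blob), structure=eight)
            assert n_in == n_out


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

class TestSkeletonizeMask:
    def test_horizontal_bar_two_endpoints(self):
        mask = PixelMask(frozenset(
            (r, c) for r in range(5, 8) for c in range(3, 23)))
        sk = skeletonize_mask(mask, (12, 30))
        assert len(sk.endpoints) == 2
        rows = {r for r, _ in sk.pixels}
        assert rows == {6}
        assert 16 <= len(sk.pixels) <= 20

    def test_single_pixel_mask_is_its_own_pole(self):
        sk = skeletonize_mask(PixelMask(frozenset({(4, 4)})), (9, 9))
        assert sk.pixels == frozenset({(4, 4)})
        assert sk.endpoints == frozenset({(4, 4)})

    def test_l_shape_two_endpoints(self):
        pixels = {(r, c) for r in range(2, 16) for c in range(2, 5)}
        pixels |= {(r, c) for r in range(13, 16) for c in range(2, 16)}
        sk = skeletonize_mask(PixelMask(frozenset(pixels)), (20, 20))
        assert len(sk.endpoints) == 2


# ---------------------------------------------------------------------------
# Adjusted area / poles / reconstruction
# ---------------------------------------------------------------------------

def _interior_band(edges):
    rr = np.arange(edges.shape[0])
    return [(r, c) for r in range(5, 11) for c in range(3, 37)]


class TestAdjustSkeletonArea:
    def test_midline_skeleton_is_kept(self, straight_cell):
        skel = Skeleton(frozenset((7, c) for c in range(6, 34)))
        grown = adjust_skeleton_area(skel, straight_cell, 3)
        assert skel.pixels <= grown

    def test_empty_edge_map_loses_cell(self):
        skel = Skeleton(frozenset({(5, 5)}))
        with pytest.raises(CellLostError):
            adjust_skeleton_area(skel, np.zeros((10, 10), bool), 3)

    def test_off_midline_skeleton_recentres(self, straight_cell):
        # 1 px off the midline grows to the same interior band (full-length
        # skeletons, so both reach every in-band column)
        mid = Skeleton(frozenset((7, c) for c in range(3, 37)))
        off = Skeleton(frozenset((8, c) for c in range(3, 37)))
        assert adjust_skeleton_area(mid, straight_cell, 3) == \
            adjust_skeleton_area(off, straight_cell, 3)

    def test_growth_cannot_cross_the_contour(self, straight_cell):
        skel = Skeleton(frozenset((7, c) for c in range(6, 34)))
        grown = adjust_skeleton_area(skel, straight_cell, 3)
        rows = {r for r, _ in grown}
        assert rows <= set(range(5, 11))  # strictly between the edge lines


class TestElongatePoles:
    def test_open_corridor_grows_forward(self, straight_cell):
        # skeleton ending mid-cell: admitted pixels lie ahead of the pole
        skel = Skeleton(frozenset((7, c) for c in range(6, 20)))
        poles = elongate_poles(skel, straight_cell, SegParams(),
                               prev_area=120)
        ahead = [p for p in poles if p[1] >= 20]
        behind = [p for p in poles if p[1] < 6]
        assert ahead
        assert not [p for p in ahead if not (4 < p[0] < 11)]
        assert not behind or all(p[1] >= 3 for p in behind)

    def test_zero_radius_probes_nothing(self, straight_cell):
        skel = Skeleton(frozenset((7, c) for c in range(6, 20)))
        poles = elongate_poles(skel, straight_cell,
                               SegParams(max_pole_elongation=0),
                               prev_area=120)
        assert poles == frozenset()

    def test_area_budget_caps_admission(self, straight_cell):
        skel = Skeleton(frozenset((7, c) for c in range(6, 20)))
        small = elongate_poles(skel, straight_cell,
                               SegParams(max_area_increase=0), prev_area=98)
        big = elongate_poles(skel, straight_cell,
                             SegParams(max_area_increase=200), prev_area=98)
        assert len(small) < len(big)


class TestReconstruct:
    def test_single_pixel_disk(self):
        mask = reconstruct({(10, 10)}, 3, (21, 21))
        assert mask.area == 29
        assert mask.pixels == frozenset(
            (10 + dr, 10 + dc) for dr, dc in euclidean_disk_reference(3))

    def test_zero_radius_is_identity(self):
        guide = {(2, 2), (2, 3), (3, 3)}
        assert reconstruct(guide, 0, (6, 6)).pixels == frozenset(guide)

    def test_dilation_bounds(self, rng):
        for _ in range(25):
            pts = {(int(r), int(c)) for r, c in
                   zip(rng.integers(10, 30, 12), rng.integers(10, 30, 12))}
            w = int(rng.integers(1, 4))
            # keep a single guide cluster so the largest-component cleanup
            # does not drop guide pixels
            seed_r, seed_c = next(iter(pts))
            pts = {(r, c) for r, c in pts
                   if abs(r - seed_r) <= w and abs(c - seed_c) <= w}
            out = reconstruct(pts, w, (40, 40))
            assert frozenset(pts) <= out.pixels
            allowed = {(r + dr, c + dc) for r, c in pts
                       for dr, dc in euclidean_disk_reference(w)}
            assert out.pixels <= allowed


# ---------------------------------------------------------------------------
# Frame propagation
# ---------------------------------------------------------------------------

class TestSegmentFrame:
    def test_isolated_cell_is_order_independent(self, default_movie):
        stacks, truth = default_movie
        img = stacks["phase"].images8[1]
        masks = sorted(truth.masks_at(0).items())
        res_fwd, _ = segment_frame(masks, img, SegParams(), frame_index=1)
        res_rev, _ = segment_frame(masks[::-1], img, SegParams(),
                                   frame_index=1)
        assert dict(res_fwd).keys() == dict(res_rev).keys()
        for name in dict(res_fwd):
            # A and B never touch at frame 1: order cannot matter
            assert dict(res_fwd)[name].pixels == dict(res_rev)[name].pixels

    def test_round_robin_conservation(self, tracked_project):
        project, truth = tracked_project
        for f in range(truth.n_frames):
            seen = set()
            for name in truth.label_of:
                if project.db.has_roi(name, f):
                    mask, _ = project.db.load_roi(name, f)
                    assert seen.isdisjoint(mask.pixels), (name, f)
                    seen |= mask.pixels

    def test_contested_strip_goes_to_earlier_cell(self):
        # two parallel tubes with no edge between them: the shared strip is
        # claimed by the alphabetically earlier cell
        edges = np.zeros((26, 40), dtype=bool)
        edges[4, 2:38] = True      # top contour of A
        edges[18, 2:38] = True     # bottom contour of B; no inner contours
        edges[4:19, 2] = True
        edges[4:19, 37] = True
        img = np.full((26, 40), 120, np.uint8)
        img[5:18, 3:37] = 60
        prev = [
            ("A", PixelMask(frozenset(
                (r, c) for r in range(5, 11) for c in range(6, 34)), 0)),
            ("B", PixelMask(frozenset(
                (r, c) for r in range(12, 18) for c in range(6, 34)), 0)),
        ]
        res, fail = segment_frame(prev, img, SegParams(), frame_index=1,
                                  edge_map=edges)
        assert not fail
        out = dict(res)
        assert not (out["A"].pixels & out["B"].pixels)
        # A is processed first and may hold strip pixels; B must not hold
        # pixels inside A's previous territory
        a_prev = prev[0][1].pixels
        assert not (out["B"].pixels & a_prev)

    def test_failures_do_not_abort_other_cells(self, default_movie):
        stacks, truth = default_movie
        img = stacks["phase"].images8[1]
        masks = dict(truth.masks_at(0))
        # a mask parked on empty background has no nearby edges
        masks["C"] = PixelMask(
            frozenset((r, c) for r in range(2, 5) for c in range(2, 12)), 0)
        res, fail = segment_frame(sorted(masks.items()), img, SegParams(),
                                  frame_index=1)
        assert set(fail) == {"C"}
        assert set(dict(res)) == {"A", "B"}
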