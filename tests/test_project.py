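"""Workflow orchestration: exclusions, manual corrections, recovery from
corrupted frames, idempotence."""

import numpy as np
import pytest

import mycotrack as mt
from mycotrack.benchmark import analyze_simulated
from mycotrack.errors import ParameterError
from mycotrack.stack import set_frame_metadata
from mycotrack.synthetic import corrupt


def _small_movie(seed=4, n_frames=10):
    return mt.simulate(mt.SimConfig(seed=seed, n_frames=n_frames,
                                    divisions_enabled=False))


def _seeded_project(stacks, truth, db_path=":memory:"):
    project = mt.Project(mt.ProjectDB(db_path), stacks)
    for name, mask in truth.masks_at(0).items():
        project.create_initial_cell(name, mask, 0)
    return project


class TestExclusion:
    def test_excluded_frame_is_skipped_and_bridged(self):
        stacks, truth = _small_movie()
        for st in stacks.values():
            set_frame_metadata(st, 3, excluded=True)
        project = _seeded_project(stacks, truth)
        project.segment_range(["A", "B"], range(1, 6))
        assert not project.db.has_roi("A", 3)
        # frame 4 was propagated from frame 2 across the gap
        assert project.db.has_roi("A", 4)

    def test_missing_seed_is_a_precondition_error(self):
        stacks, truth = _small_movie()
        project = mt.Project(mt.ProjectDB(":memory:"), stacks)
        project.create_initial_cell("A", truth.mask("A", 0), 0)
        project.lineage.create_initial_cell("Z", truth.mask("B", 0), 5)
        with pytest.raises(ParameterError, match="Z"):
            project.segment_range(["Z"], range(1, 3))


class TestManualCorrection:
    def test_propagation_reseeds_from_manual_mask(self):
        stacks, truth = _small_movie()
        project = _seeded_project(stacks, truth)
        project.segment_range(["A", "B"], range(1, 4))
        auto_then, _ = project.db.load_roi("A", 4) if \
            project.db.has_roi("A", 4) else (None, None)
        project.correct_mask("A", 3, truth.mask("A", 3))
        project.segment_range(["A", "B"], range(4, 5))
        new_mask, prov = project.db.load_roi("A", 4)
        assert prov == "auto"
        # the frame-4 result must be seeded from the corrected frame-3 mask
        manual, _ = project.db.load_roi("A", 3)
        inter = len(new_mask.pixels & manual.pixels)
        assert inter / manual.area > 0.7

    def test_rerunning_is_idempotent(self):
        stacks, truth = _small_movie()
        project = _seeded_project(stacks, truth)
        project.segment_range(["A", "B"], range(1, 6))
        first = {(c, f): project.db.load_roi(c, f)[0].pixels
                 for c in "AB" for f in range(1, 6)}
        project.segment_range(["A", "B"], range(1, 6))
        second = {(c, f): project.db.load_roi(c, f)[0].pixels
                  for c in "AB" for f in range(1, 6)}
        assert first == second


class TestCorruptedFrame:
    def test_flagged_then_recovered_after_manual_fix(self):
        stacks, truth = _small_movie(seed=6, n_frames=10)
        stacks = dict(stacks)
        stacks["phase"] = corrupt(stacks["phase"], 4, "dark")
        project = _seeded_project(stacks, truth)
        report = project.segment_range(["A", "B"], range(1, 8))
        assert report.failed > 0
        assert report.needs_attention
        # the user replaces the lost cells' masks on the bad frame with
        # truth outlines; propagation then resumes and recovers
        for cell in report.needs_attention:
            project.correct_mask(cell, 4, truth.mask(cell, 4))
        report2 = project.segment_range(list(report.needs_attention),
                                        range(5, 8))
        assert report2.failed == 0
        for cell in report.needs_attention:
            mask, _ = project.db.load_roi(cell, 7)
            t = truth.mask(cell, 7)
            iou = len(mask.pixels & t.pixels) / len(mask.pixels | t.pixels)
            assert iou >= 0.75

    def test_excluding_the_corrupted_frame_bridges_it(self):
        stacks, truth = _small_movie(seed=6, n_frames=10)
        stacks = dict(stacks)
        stacks["phase"] = corrupt(stacks["phase"], 4, "dark")
        for st in stacks.values():
            set_frame_metadata(st, 4, excluded=True)
        project = _seeded_project(stacks, truth)
        report = project.segment_range(["A", "B"], range(1, 8))
        assert report.failed == 0
        assert project.db.has_roi("A", 5)


class TestLifetimes:
    def test_divided_parent_is_not_resegmented(self, tracked_project):
        project, truth = tracked_project
        parent, frame = truth.divisions()[0]
        rec = project.lineage[parent]
        assert rec.fate == "divided"
        for f in range(frame, truth.n_frames):
            assert not project.db.has_roi(parent, f)

    def test_ignored_cell_gets_no_auto_masks(self):
        stacks, truth = _small_movie()
        project = _seeded_project(stacks, truth)
        project.set_cell_state("B", 3, "ignored")
        project.segment_range(["A", "B"], range(1, 6))
        assert project.db.has_roi("B", 2)
        assert not project.db.has_roi("B", 3)
        assert not project.db.has_roi("B", 5)

    def test_interdivision_time_through_project(self, tracked_project):
        project, truth = tracked_project
        parent, frame = truth.divisions()[0]
        minutes, censored = project.interdivision_time(parent)
        rec = project.lineage[parent]
        assert minutes == (frame - rec.birth_frame) * 10.0
        assert censored  # initial cell present at movie start
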