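"""Project orchestration: the movie-analysis workflow end to end.

A :class:`Project` ties together the per-channel image stacks, the lineage
registry and the SQLite datastore, and exposes the workflow of the
platform: seed initial cells, propagate selections frame by frame
(persisting each immediately), ingest user division annotations and manual
corrections, measure, and derive time-courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (CellLostError, DatastoreError, DegenerateHistogramError,
                     LineageError, NotDefinedError, ParameterError)
from .lineage import Lineage
from .masks import PixelMask
from .measure import (exponential_rate, linear_rate, mask_length_um,
                      measure_background, measure_roi, ratio_stats)
from .segmentation import SegParams, build_edge_map, segment_frame
from .stack import FrameStack
from .store import ProjectDB


@dataclass
class SegmentReport:
    """Outcome counts of one segment_range run."""

    auto: int = 0
    manual: int = 0
    failed: int = 0
    needs_attention: dict[str, int] = field(default_factory=dict)
    # cell -> frame at which propagation stopped


class Project:
    """One time-lapse analysis project."""

    def __init__(self, db: ProjectDB, stacks: dict[str, FrameStack],
                 params: SegParams | None = None,
                 threshold_method: str = "isodata"):
        if not stacks:
            raise ParameterError("a project needs at least one channel")
        shapes = {s.shape for s in stacks.values()}
        if len(shapes) > 1:
            raise ParameterError("all channels must share image dimensions")
        self.db = db
        self.stacks = stacks
        self.params = params or SegParams()
        self.threshold_method = threshold_method
        self.lineage = Lineage()
        ref = next(iter(stacks.values()))
        self.times_min = list(ref.times_min)
        self.pixel_size_um = ref.pixel_size_um
        for name, st in stacks.items():
            db.save_channel(name)
        for i, t in enumerate(self.times_min):
            db.save_frame(i, t, excluded=ref.excluded[i], note=ref.notes[i])
        db.set_meta("pixel_size_um", self.pixel_size_um)
        self._load_lineage()

    def _load_lineage(self) -> None:
        """Rehydrate cell records persisted by an earlier session."""
        from .lineage import CellRecord

        rows = self.db.conn.execute(
            "SELECT name, parent, birth_frame, end_frame, fate FROM cell "
            "ORDER BY name").fetchall()
        for name, parent, birth, end, fate in rows:
            self.lineage.cells[name] = CellRecord(
                name=name, parent=parent, birth_frame=birth,
                end_frame=end, fate=fate)
        for cell, frame, state in self.db.conn.execute(
                "SELECT cell, frame, state FROM cell_state").fetchall():
            if cell in self.lineage.cells:
                self.lineage.cells[cell].states[frame] = state

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.stacks.values())).shape

    def _stack(self, channel: str) -> FrameStack:
        try:
            return self.stacks[channel]
        except KeyError:
            raise ParameterError(f"no channel {channel!r} in project") \
                from None

    def frame_excluded(self, frame: int) -> bool:
        return any(s.excluded[frame] for s in self.stacks.values())

    def _sync_cell(self, name: str) -> None:
        rec = self.lineage[name]
        self.db.save_cell(rec.name, rec.parent, rec.birth_frame,
                          rec.end_frame, rec.fate)

    # -- seeding, division, state -----------------------------------------

    def create_initial_cell(self, name: str, mask: PixelMask,
                            frame: int = 0):
        rec = self.lineage.create_initial_cell(name, mask, frame)
        self._sync_cell(name)
        self.db.save_roi(name, mask, provenance="manual")
        self.db.log_event("create_initial_cell", frame, cell=name)
        return rec

    def record_division(self, parent: str, frame: int, mask_a: PixelMask,
                        mask_b: PixelMask):
        if self.frame_excluded(frame):
            raise LineageError(
                f"cannot annotate a division on excluded frame {frame}")
        a, b = self.lineage.record_division(
            parent, frame,
            PixelMask(mask_a.pixels, frame), PixelMask(mask_b.pixels, frame))
        for rec, mask in ((a, mask_a), (b, mask_b)):
            self._sync_cell(rec.name)
            self.db.save_roi(rec.name, PixelMask(mask.pixels, frame),
                             provenance="manual")
        self._sync_cell(parent)
        self.db.log_event("division", frame, parent=parent,
                          daughters=[a.name, b.name])
        return a, b

    def set_cell_state(self, name: str, frame: int, state: str):
        rec = self.lineage.set_cell_state(name, frame, state)
        self._sync_cell(name)
        self.db.conn.execute(
            "INSERT OR REPLACE INTO cell_state (cell, frame, state) "
            "VALUES (?, ?, ?)", (name, frame, state))
        self.db.conn.commit()
        self.db.log_event("set_state", frame, cell=name, state=state)
        return rec

    def correct_mask(self, name: str, frame: int, mask: PixelMask) -> None:
        """Ingest a manual correction; later frames re-seed from it."""
        self.db.save_roi(name, PixelMask(mask.pixels, frame),
                         provenance="manual")
        self.db.log_event("manual_correction", frame, cell=name)

    def interdivision_time(self, name: str) -> tuple[float, bool]:
        return self.lineage.interdivision_time(name, self.times_min)

    # -- segmentation ------------------------------------------------------

    def _previous_mask(self, cell: str, frame: int) -> PixelMask | None:
        """Latest stored mask strictly before ``frame`` on a usable frame."""
        rec = self.lineage[cell]
        for f in range(frame - 1, rec.birth_frame - 1, -1):
            if self.frame_excluded(f):
                continue
            if self.db.has_roi(cell, f):
                mask, _ = self.db.load_roi(cell, f)
                return mask
        return None

    def segment_range(self, cells: list[str], frames: range,
                      channel: str = "phase",
                      params: SegParams | None = None) -> SegmentReport:
        """Propagate the listed cells across a frame range.

        Every cell must already have a selection on a frame preceding the
        range (its seed).  Excluded frames are skipped (propagation crosses
        the gap); a cell hitting a cell-lost error is flagged
        needs-attention and stops, the others continue.  Each selection is
        persisted the moment it is computed.
        """
        params = params or self.params
        stack = self._stack(channel)
        report = SegmentReport()
        first = frames[0]
        active = []
        for name in sorted(cells):
            rec = self.lineage[name]
            if self._previous_mask(name, max(first, rec.birth_frame)) is None \
                    and not self.db.has_roi(name, rec.birth_frame):
                raise ParameterError(
                    f"cell {name!r} has no seed mask before frame {first}")
            active.append(name)
        self.db.log_event("segment_range", first, cells=sorted(cells),
                          frames=[frames[0], frames[-1]], channel=channel,
                          params=[params.cell_width,
                                  params.max_pole_elongation,
                                  params.max_area_increase],
                          threshold=self.threshold_method)

        stopped: set[str] = set()
        for f in frames:
            if self.frame_excluded(f):
                continue
            prev_masks = []
            fixed_masks = []
            for name in active:
                rec = self.lineage[name]
                if name in stopped or not rec.alive_at(f):
                    continue
                if self.db.has_roi(name, f):
                    mask, prov = self.db.load_roi(name, f)
                    if prov == "manual":
                        # user-supplied selection wins; it claims its pixels
                        fixed_masks.append((name, mask))
                        report.manual += 1
                        continue
                if f == rec.birth_frame:
                    continue  # birth mask is the manual seed itself
                prev = self._previous_mask(name, f)
                if prev is not None:
                    prev_masks.append((name, prev))
            if not prev_masks:
                continue
            try:
                edge_map = build_edge_map(stack.images8[f],
                                          self.threshold_method)
            except DegenerateHistogramError:
                # unusable frame (e.g. intensity collapse): every cell due
                # for propagation here needs the user's attention
                for name, _ in prev_masks:
                    report.failed += 1
                    report.needs_attention[name] = f
                    stopped.add(name)
                    self.db.log_event("needs_attention", f, cell=name,
                                      reason="frame has no usable contrast")
                continue
            results, failures = segment_frame(
                prev_masks, stack.images8[f], params,
                method=self.threshold_method, frame_index=f,
                edge_map=edge_map, fixed_masks=fixed_masks)
            for name, mask in results:
                self.db.save_roi(name, mask, provenance="auto")
                report.auto += 1
            for name, err in failures.items():
                report.failed += 1
                report.needs_attention[name] = f
                stopped.add(name)
                self.db.log_event("needs_attention", f, cell=name,
                                  reason=err.reason)
        return report

    # -- measurement -------------------------------------------------------

    def set_background(self, mask: PixelMask) -> None:
        self.db.save_background_roi(mask)
        self.db.log_event("set_background", None, area=mask.area)

    def measure(self, cells: list[str] | None = None,
                frames: list[int] | None = None,
                channels: list[str] | None = None,
                erode_px: int = 0) -> int:
        """Measure stored selections on the original images.

        Geometry variables (area, length) are stored under channel '' once
        per (cell, frame); intensity statistics per fluorescence channel.
        If a background region is defined, per-frame background means are
        stored and ``mean_corrected`` rows are added; with no background
        the corrected variable is simply absent.  Returns the number of
        (cell, frame) selections measured.
        """
        channels = channels or [c for c in self.stacks if c != "phase"]
        if cells is None:
            cells = sorted(self.lineage.cells)
        rows = []
        bg_mask = self.db.load_background_roi()
        shape = self.shape
        measured = 0
        all_frames = frames if frames is not None else \
            range(len(self.times_min))
        usable = [f for f in all_frames if not self.frame_excluded(f)]

        bg_means: dict[tuple[int, str], float] = {}
        if bg_mask is not None:
            for ch in channels:
                st = self._stack(ch)
                means = measure_background(bg_mask, st.originals, usable)
                for f, v in means.items():
                    self.db.save_background_mean(f, ch, v)
                    bg_means[(f, ch)] = v

        for name in cells:
            rec = self.lineage[name]
            for f in usable:
                if not (rec.birth_frame <= f and
                        (rec.end_frame is None or f <= rec.end_frame)):
                    continue
                if rec.state_at(f) != "active":
                    continue
                if not self.db.has_roi(name, f):
                    continue
                mask, _ = self.db.load_roi(name, f)
                if bg_mask is not None and mask.intersects(bg_mask):
                    import warnings

                    warnings.warn(
                        f"background region overlaps cell {name} at frame "
                        f"{f}", stacklevel=2)
                area_px = mask.area
                rows.append((name, f, "", "area_px", float(area_px)))
                rows.append((name, f, "", "area_um2",
                             area_px * self.pixel_size_um ** 2))
                rows.append((name, f, "", "length_um",
                             mask_length_um(mask, shape, self.pixel_size_um)))
                for ch in channels:
                    st = self._stack(ch)
                    stats = measure_roi(mask, st.originals[f], erode_px)
                    for var in ("mean", "sd", "min", "max", "integrated"):
                        rows.append((name, f, ch, var, stats[var]))
                    bg = bg_means.get((f, ch))
                    if bg is not None:
                        rows.append((name, f, ch, "mean_corrected",
                                     stats["mean"] - bg))
                measured += 1
        self.db.save_measurements(rows)
        self.db.log_event("measure", None, cells=list(cells),
                          channels=list(channels), erode_px=erode_px,
                          n_selections=measured)
        return measured

    def _variable(self, variable: str, channel: str = ""
                  ) -> dict[tuple[str, int], float]:
        rows = self.db.conn.execute(
            "SELECT cell, frame, value FROM measurement "
            "WHERE variable=? AND channel=?", (variable, channel)).fetchall()
        return {(r[0], r[1]): r[2] for r in rows}

    def growth_rate(self, name: str) -> dict[str, float]:
        """Linear elongation rate (um/h) and exponential area rate (1/h)."""
        rec = self.lineage[name]
        lengths, areas, times = [], [], []
        for f in range(rec.birth_frame, (rec.end_frame
                                         if rec.end_frame is not None
                                         else len(self.times_min) - 1) + 1):
            row_l = self.db.conn.execute(
                "SELECT value FROM measurement WHERE cell=? AND frame=? AND "
                "variable='length_um'", (name, f)).fetchone()
            row_a = self.db.conn.execute(
                "SELECT value FROM measurement WHERE cell=? AND frame=? AND "
                "variable='area_um2'", (name, f)).fetchone()
            if row_l is None or row_a is None:
                continue
            lengths.append(row_l[0])
            areas.append(row_a[0])
            times.append(self.times_min[f])
        if len(times) < 2:
            raise NotDefinedError(
                f"cell {name!r} has fewer than 2 measured frames")
        t = np.asarray(times)
        return {
            "elongation_um_per_h": linear_rate(t, np.asarray(lengths)),
            "area_exp_per_h": exponential_rate(t, np.asarray(areas)),
        }

    def ratio_timecourse(self, num_channel: str = "ch1",
                         den_channel: str = "ch2"
                         ) -> dict[int, tuple[float, float, int, int]]:
        """Per-frame across-cell mean/SD of the corrected intensity ratio.

        Requires background-corrected means for both channels; see
        :meth:`ProjectDB.ratio_timecourse_sql` for the equivalent shipped
        SQL.  Returns {frame: (mean, sd, n_cells, n_excluded)}.
        """
        num = self._variable("mean_corrected", num_channel)
        den = self._variable("mean_corrected", den_channel)
        if not num or not den:
            raise DatastoreError(
                "background-corrected means missing; define a background "
                "region and run measure() first")
        return ratio_stats(num, den)
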