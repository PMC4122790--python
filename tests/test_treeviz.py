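"""Lineage-tree layout determinism and SVG style fidelity."""

from xml.etree import ElementTree as ET

import numpy as np
import pytest

from mycotrack.errors import LineageError
from mycotrack.lineage import Lineage
from mycotrack.masks import PixelMask
from mycotrack.treeviz import (StyleMap, count_crossings, layout_tree,
                               render_tree)

TIMES = [10.0 * i for i in range(120)]


def _mask(*pixels):
    return PixelMask(frozenset(pixels))


def _complete_lineage(generations: int) -> Lineage:
    lin = Lineage()
    lin.create_initial_cell("A", _mask((0, 0)), 0)
    frontier = ["A"]
    frame = 10
    for _ in range(generations):
        nxt = []
        for name in frontier:
            lin.record_division(name, frame, _mask((0, 0)), _mask((1, 1)))
            nxt += [name + "A", name + "B"]
        frontier = nxt
        frame += 10
    for name in frontier:
        lin.cells[name].end_frame = frame + 5
    return lin


class TestLayout:
    def test_single_branch_spans_whole_movie(self):
        lin = Lineage()
        lin.create_initial_cell("A", _mask((0, 0)), 0)
        lin.cells["A"].end_frame = 100
        layout = layout_tree(lin["A"], lin, TIMES[:101])
        node = layout.node("A")
        assert (node.y_birth, node.y_end) == (0.0, 1000.0)

    def test_division_y_shape(self):
        lin = Lineage()
        lin.create_initial_cell("A", _mask((0, 0)), 0)
        lin.record_division("A", 12, _mask((0, 0)), _mask((1, 1)))
        for d in ("AA", "AB"):
            lin.cells[d].end_frame = 30
        layout = layout_tree(lin["A"], lin, TIMES)
        a = layout.node("A")
        assert a.y_end - a.y_birth == 120.0  # parent branch length
        assert layout.node("AA").x < layout.node("AB").x  # A left, B right
        assert a.x == pytest.approx(
            0.5 * (layout.node("AA").x + layout.node("AB").x))

    @pytest.mark.parametrize("generations", [1, 2, 3, 4])
    def test_complete_lineages_have_no_crossings(self, generations):
        lin = _complete_lineage(generations)
        layout = layout_tree(lin["A"], lin, TIMES)
        leaves = [n for n in layout.nodes
                  if len(n.name) == generations + 1]
        assert len(leaves) == 2 ** generations
        assert len({n.x for n in leaves}) == len(leaves)  # disjoint lanes
        assert count_crossings(layout) == 0

    def test_missing_daughter_is_integrity_error(self):
        lin = _complete_lineage(1)
        del lin.cells["AB"]
        with pytest.raises(LineageError):
            layout_tree(lin["A"], lin, TIMES)


def _render(lin, style, out, width_values, color_values, times):
    layout = layout_tree(lin["A"], lin, times)
    report = render_tree(layout, style, out, width_values, color_values,
                         times, px_per_min=0.5)
    return layout, report, ET.parse(out).getroot()


def _branches(svg_root):
    ns = "{http://www.w3.org/2000/svg}"
    return [el for el in svg_root.iter(ns + "line")
            if el.get("class") == "branch"]


class TestRender:
    def test_branch_vertical_extents_equal_lifetimes(self, tmp_path):
        lin = _complete_lineage(2)
        values = {(n, f): 1.0 for n in lin.cells for f in range(60)}
        layout, _, svg = _render(lin, StyleMap(), tmp_path / "t.svg",
                                 values, values, TIMES[:60])
        spans = {}
        for el in _branches(svg):
            cell = el.get("data-cell")
            y1, y2 = float(el.get("y1")), float(el.get("y2"))
            lo, hi = spans.get(cell, (y1, y2))
            spans[cell] = (min(lo, y1, y2), max(hi, y1, y2))
        for node in layout.nodes:
            lo, hi = spans[node.name]
            assert hi - lo == pytest.approx(
                (node.y_end - node.y_birth) * 0.5)

    def test_constant_variables_give_uniform_style(self, tmp_path):
        lin = _complete_lineage(1)
        values = {(n, f): 5.0 for n in lin.cells for f in range(40)}
        _, _, svg = _render(lin, StyleMap(), tmp_path / "u.svg",
                            values, values, TIMES[:40])
        widths = {el.get("stroke-width") for el in _branches(svg)}
        colors = {el.get("stroke") for el in _branches(svg)}
        assert len(widths) == 1
        assert len(colors) == 1

    def test_width_follows_variable_affinely(self, tmp_path):
        lin = Lineage()
        lin.create_initial_cell("A", _mask((0, 0)), 0)
        lin.cells["A"].end_frame = 20
        wvals = {("A", f): float(f) for f in range(21)}
        cvals = {("A", f): 1.0 for f in range(21)}
        style = StyleMap(min_px=1.0, max_px=9.0)
        _, _, svg = _render(lin, style, tmp_path / "w.svg", wvals, cvals,
                            TIMES[:21])
        seq = sorted((int(el.get("data-frame")),
                      float(el.get("stroke-width")))
                     for el in _branches(svg))
        frames = np.array([f for f, _ in seq], dtype=float)
        widths = np.array([w for _, w in seq])
        # monotone widening, affine in the sampled variable
        assert np.all(np.diff(widths) > 0)
        fit = np.polyfit(frames, widths, 1)
        assert np.allclose(np.polyval(fit, frames), widths, atol=0.01)

    def test_color_class_changes_after_event_line(self, tmp_path):
        lin = Lineage()
        lin.create_initial_cell("A", _mask((0, 0)), 0)
        lin.cells["A"].end_frame = 20
        switch = 10
        wvals = {("A", f): 1.0 for f in range(21)}
        cvals = {("A", f): (600.0 if f >= switch else 100.0)
                 for f in range(21)}
        layout = layout_tree(lin["A"], lin, TIMES[:21],
                             annotations=[(100.0, "switch")])
        render_tree(layout, StyleMap(colormap="viridis"),
                    tmp_path / "c.svg", wvals, cvals, TIMES[:21])
        svg = ET.parse(tmp_path / "c.svg").getroot()
        pre = {el.get("stroke") for el in _branches(svg)
               if int(el.get("data-frame")) < switch}
        post = {el.get("stroke") for el in _branches(svg)
                if int(el.get("data-frame")) >= switch}
        assert pre.isdisjoint(post)
        ns = "{http://www.w3.org/2000/svg}"
        annotations = [el for el in svg.iter(ns + "line")
                       if el.get("class") == "annotation"]
        assert len(annotations) == 1

    def test_missing_samples_reported_and_drawn_neutral(self, tmp_path):
        lin = Lineage()
        lin.create_initial_cell("A", _mask((0, 0)), 0)
        lin.cells["A"].end_frame = 10
        wvals = {("A", f): 1.0 for f in range(5)}  # frames 5.. missing
        cvals = {("A", f): 1.0 for f in range(11)}
        _, report, svg = _render(lin, StyleMap(), tmp_path / "m.svg",
                                 wvals, cvals, TIMES[:11])
        assert report.missing
        assert any(el.get("stroke") == "#bbbbbb" for el in _branches(svg))
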