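"""Lineage-tree layout and SVG rendering.

One tree is drawn per initial cell.  Time runs down the vertical axis;
branch points are division events, so a branch's vertical extent equals the
cell's lifetime in minutes.  Two measured variables decorate the tree: one
is mapped linearly to branch *width*, the other through a colormap to
branch *color*, both sampled per frame (piecewise-constant along the
branch).  Horizontal event lines (e.g. a medium switch) can be annotated.

Layout is deterministic: leaves get unit lanes in A-before-B order and an
internal cell sits at the midpoint of its daughters' lanes, which makes
sibling subtrees occupy disjoint lane intervals — no branch ever crosses
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .errors import LineageError, ParameterError
from .lineage import CellRecord, Lineage, daughter_names


@dataclass
class TreeNode:
    name: str
    x: float          # unitless lane coordinate
    y_birth: float    # minutes
    y_end: float      # minutes
    fate: str | None


@dataclass
class TreeLayout:
    nodes: list[TreeNode]
    edges: list[tuple[str, str]]          # parent -> child connectors
    annotations: list[tuple[float, str]]  # (time_min, label)
    t_min: float
    t_max: float

    def node(self, name: str) -> TreeNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise LineageError(f"no node {name!r} in layout")


@dataclass
class StyleMap:
    """Variable-to-style mapping for branch width and color."""

    width_var: str = "area_um2"
    color_var: str = "ch1_mean_corrected"
    min_px: float = 1.0
    max_px: float = 8.0
    colormap: str = "viridis"
    width_domain: tuple[float, float] | None = None  # None: data min/max
    color_domain: tuple[float, float] | None = None

    def width_of(self, value: float, domain: tuple[float, float]) -> float:
        lo, hi = domain
        if hi <= lo:
            return 0.5 * (self.min_px + self.max_px)
        frac = np.clip((value - lo) / (hi - lo), 0.0, 1.0)
        return self.min_px + frac * (self.max_px - self.min_px)

    def color_of(self, value: float, domain: tuple[float, float]) -> str:
        import matplotlib

        lo, hi = domain
        frac = 0.5 if hi <= lo else float(
            np.clip((value - lo) / (hi - lo), 0.0, 1.0))
        r, g, b, _ = matplotlib.colormaps[self.colormap](frac)
        return f"#{int(r * 255):02x}{int(g * 255):02x}{int(b * 255):02x}"


def layout_tree(root: CellRecord, lineage: Lineage,
                times_min: list[float],
                annotations: list[tuple[float, str]] | None = None
                ) -> TreeLayout:
    """Recursive lane layout of one initial cell's subtree."""
    if root.parent is not None:
        raise LineageError(f"{root.name!r} is not an initial cell")
    last = len(times_min) - 1

    def y_end_of(rec: CellRecord) -> float:
        if rec.fate == "divided":
            return times_min[rec.end_frame + 1]  # division instant
        end = rec.end_frame if rec.end_frame is not None else last
        return times_min[min(end, last)]

    nodes: list[TreeNode] = []
    edges: list[tuple[str, str]] = []
    next_lane = [0.0]

    def place(rec: CellRecord) -> float:
        kids = []
        if rec.fate == "divided":
            for dname in daughter_names(rec.name):
                if dname not in lineage:
                    raise LineageError(
                        f"divided cell {rec.name!r} missing daughter "
                        f"{dname!r}")
                kids.append(lineage[dname])
        if not kids:
            x = next_lane[0]
            next_lane[0] += 1.0
        else:
            xs = [place(k) for k in kids]  # A first, then B
            x = 0.5 * (xs[0] + xs[-1])
            for k in kids:
                edges.append((rec.name, k.name))
        nodes.append(TreeNode(rec.name, x, times_min[rec.birth_frame],
                              y_end_of(rec), rec.fate))
        return x

    place(root)
    return TreeLayout(nodes=nodes, edges=edges,
                      annotations=list(annotations or []),
                      t_min=min(n.y_birth for n in nodes),
                      t_max=max(n.y_end for n in nodes))


def count_crossings(layout: TreeLayout) -> int:
    """Brute-force count of intersecting branch pairs (0 for a sound tree).

    Branches are vertical segments at their lane coordinate; two branches
    cross if their lanes coincide and their time intervals overlap beyond a
    shared endpoint.
    """
    segs = [(n.x, n.y_birth, n.y_end) for n in layout.nodes]
    crossings = 0
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            (x1, a1, b1), (x2, a2, b2) = segs[i], segs[j]
            if x1 == x2 and min(b1, b2) - max(a1, a2) > 0:
                crossings += 1
    return crossings


@dataclass
class RenderReport:
    missing: list[tuple[str, int, str]] = field(default_factory=list)
    # (cell, frame, variable) that had no measurement; drawn neutral


def _sample(values: dict[tuple[str, int], float], cell: str,
            frame: int) -> float | None:
    return values.get((cell, frame))


def render_tree(layout: TreeLayout, style: StyleMap, out,
                width_values: dict[tuple[str, int], float],
                color_values: dict[tuple[str, int], float],
                times_min: list[float],
                px_per_min: float = 0.5, lane_px: float = 40.0,
                margin: float = 60.0) -> RenderReport:
    """Write the decorated tree as an SVG file.

    ``width_values`` / ``color_values`` map (cell, frame) to the sampled
    variable values.  Branches are drawn as one vertical ``line`` element
    per frame interval (class ``branch``); missing samples are drawn in
    neutral grey at minimum width and reported.  A color bar and width
    reference legend and dashed annotation lines are included.
    """
    if px_per_min <= 0:
        raise ParameterError("px_per_min must be > 0")
    report = RenderReport()

    def wd(vals):
        v = [x for x in vals.values() if x is not None]
        return (min(v), max(v)) if v else (0.0, 1.0)

    width_domain = style.width_domain or wd(width_values)
    color_domain = style.color_domain or wd(color_values)

    def ypix(t_min: float) -> float:
        return margin + (t_min - layout.t_min) * px_per_min

    def xpix(lane: float) -> float:
        return margin + lane * lane_px

    max_lane = max(n.x for n in layout.nodes)
    width = int(xpix(max_lane) + margin + 140)
    height = int(ypix(layout.t_max) + margin)

    svg = ET.Element("svg", xmlns="http://www.w3.org/2000/svg",
                     width=str(width), height=str(height))
    ET.SubElement(svg, "rect", x="0", y="0", width=str(width),
                  height=str(height), fill="white")

    frame_of = {t: i for i, t in enumerate(times_min)}

    for node in layout.nodes:
        # frame interval covered by this branch
        f0 = frame_of[min(times_min, key=lambda t: abs(t - node.y_birth))]
        t = node.y_birth
        f = f0
        while t < node.y_end and f < len(times_min):
            t_next = min(times_min[f + 1] if f + 1 < len(times_min)
                         else node.y_end, node.y_end)
            wv = _sample(width_values, node.name, f)
            cv = _sample(color_values, node.name, f)
            if wv is None or cv is None:
                report.missing.append(
                    (node.name, f,
                     style.width_var if wv is None else style.color_var))
                stroke, swidth = "#bbbbbb", style.min_px
            else:
                stroke = style.color_of(cv, color_domain)
                swidth = style.width_of(wv, width_domain)
            ET.SubElement(
                svg, "line", x1=f"{xpix(node.x):.2f}", x2=f"{xpix(node.x):.2f}",
                y1=f"{ypix(t):.2f}", y2=f"{ypix(t_next):.2f}",
                stroke=stroke, attrib={
                    "stroke-width": f"{swidth:.3f}",
                    "class": "branch",
                    "data-cell": node.name,
                    "data-frame": str(f),
                })
            t = t_next
            f += 1
        if node.fate in ("ignored", "censored"):
            ET.SubElement(svg, "circle", cx=f"{xpix(node.x):.2f}",
                          cy=f"{ypix(node.y_end):.2f}", r="3",
                          fill="white", stroke="#555555",
                          attrib={"class": "terminus-open"})
        elif node.fate == "dead":
            ET.SubElement(svg, "circle", cx=f"{xpix(node.x):.2f}",
                          cy=f"{ypix(node.y_end):.2f}", r="3",
                          fill="#555555", attrib={"class": "terminus-dead"})

    # division connectors
    for parent, child in layout.edges:
        p, c = layout.node(parent), layout.node(child)
        ET.SubElement(svg, "line", x1=f"{xpix(p.x):.2f}",
                      x2=f"{xpix(c.x):.2f}", y1=f"{ypix(p.y_end):.2f}",
                      y2=f"{ypix(c.y_birth):.2f}", stroke="#333333",
                      attrib={"stroke-width": "1.0", "class": "connector"})

    # event annotations: dashed horizontal lines
    for t_evt, label in layout.annotations:
        y = ypix(t_evt)
        ET.SubElement(svg, "line", x1=str(int(margin / 2)),
                      x2=str(width - 140), y1=f"{y:.2f}", y2=f"{y:.2f}",
                      stroke="#cc0000", attrib={
                          "stroke-width": "1.0",
                          "stroke-dasharray": "6,4",
                          "class": "annotation"})
        txt = ET.SubElement(svg, "text", x=str(width - 135),
                            y=f"{y + 4:.2f}", fill="#cc0000",
                            attrib={"font-size": "11"})
        txt.text = label

    # legend: color bar + width reference
    bar_x, bar_y, bar_h = width - 110, margin, 120
    for i in range(24):
        frac = i / 23.0
        value = color_domain[0] + frac * (color_domain[1] - color_domain[0])
        ET.SubElement(svg, "rect", x=str(bar_x),
                      y=f"{bar_y + bar_h * (1 - frac) - bar_h / 24:.2f}",
                      width="14", height=f"{bar_h / 24 + 0.5:.2f}",
                      fill=style.color_of(value, color_domain),
                      attrib={"class": "colorbar"})
    for frac, dy in ((0.0, bar_h), (1.0, 0.0)):
        value = color_domain[0] + frac * (color_domain[1] - color_domain[0])
        txt = ET.SubElement(svg, "text", x=str(bar_x + 18),
                            y=f"{bar_y + dy + 4:.2f}",
                            attrib={"font-size": "10"})
        txt.text = f"{value:.3g}"
    cap = ET.SubElement(svg, "text", x=str(bar_x), y=f"{bar_y - 8:.2f}",
                        attrib={"font-size": "10"})
    cap.text = style.color_var
    for i, (label, value) in enumerate(
            (("min", width_domain[0]), ("max", width_domain[1]))):
        y = bar_y + bar_h + 30 + i * 16
        ET.SubElement(svg, "line", x1=str(bar_x), x2=str(bar_x + 30),
                      y1=f"{y:.2f}", y2=f"{y:.2f}", stroke="#333333",
                      attrib={"stroke-width":
                              f"{style.width_of(value, width_domain):.3f}",
                              "class": "width-legend"})
        txt = ET.SubElement(svg, "text", x=str(bar_x + 36),
                            y=f"{y + 4:.2f}", attrib={"font-size": "10"})
        txt.text = f"{style.width_var} {value:.3g}"

    Path(out).write_bytes(ET.tostring(svg))
    return report


def tree_values_from_db(db, variable: str) -> dict[tuple[str, int], float]:
    """Fetch a styling variable from the measurement table.

    ``variable`` is either a geometry variable (e.g. ``area_um2``) or a
    channel-qualified one like ``ch1_mean_corrected``.
    """
    channel, var = "", variable
    for ch in ("phase", "ch1", "ch2", "ch3"):
        if variable.startswith(ch + "_"):
            channel, var = ch, variable[len(ch) + 1:]
            break
    rows = db.conn.execute(
        "SELECT cell, frame, value FROM measurement WHERE variable=? AND "
        "channel=?", (var, channel)).fetchall()
    return {(r[0], r[1]): r[2] for r in rows}
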