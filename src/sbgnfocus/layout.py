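"""Nesting-preserving compound layout and SVG export.

The layout contract is geometric, not aesthetic: after
:func:`compound_layout`, every child bbox lies inside its parent bbox
(with a padding margin) and sibling groups do not overlap.  The
algorithm is a two-phase recursion: each compound's children are first
laid out bottom-up with a seeded spring embedder (networkx), positions
are then rescaled until no two sibling boxes collide, and the parent
bbox is fitted around its children plus padding.  Root-level nodes are
treated as children of a virtual root, so top-level components do not
overlap either.  Determinism: identical (map, config) pairs give
identical coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .model import BBox, PDMap, is_logic, is_process


@dataclass(frozen=True)
class LayoutConfig:
    """Tunables of the compound layout.

    ``ideal_edge_length`` is the spring rest length in map units;
    ``compartment_padding`` the margin kept between a container border
    and its children.  The seed fixes the spring embedder's start state.
    """

    iterations: int = 50
    ideal_edge_length: float = 120.0
    compartment_padding: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.compartment_padding < 0:
            raise ValueError("compartment_padding must be >= 0")


def _half_diag(bbox: BBox) -> float:
    return math.hypot(bbox.w, bbox.h) / 2.0


def _sibling_graph(pd_map: PDMap, siblings: list[str]) -> nx.Graph:
    """Graph over siblings; arcs between their subtrees become edges."""
    owner: dict[str, str] = {}
    for sib in siblings:
        owner[sib] = sib
        stack = [sib]
        while stack:
            for child in pd_map.children_of(stack.pop()):
                owner[child] = sib
                stack.append(child)
    g = nx.Graph()
    g.add_nodes_from(siblings)
    for arc in pd_map.arcs.values():
        s, t = owner.get(arc.source_id), owner.get(arc.target_id)
        if s is not None and t is not None and s != t:
            g.add_edge(s, t)
    return g


def _spread(pd_map: PDMap, siblings: list[str], pos: dict[str, tuple[float, float]],
            gap: float) -> dict[str, tuple[float, float]]:
    """Scale spring positions until no two sibling boxes can collide."""
    if len(siblings) < 2:
        return pos
    # deterministic jitter for coincident points
    for i, sib in enumerate(siblings):
        x, y = pos[sib]
        pos[sib] = (x + 1e-3 * math.cos(i), y + 1e-3 * math.sin(i))
    scale = 1.0
    for i, a in enumerate(siblings):
        for b in siblings[i + 1:]:
            dist = math.hypot(pos[a][0] - pos[b][0], pos[a][1] - pos[b][1])
            need = _half_diag(pd_map.glyphs[a].bbox) + _half_diag(pd_map.glyphs[b].bbox) + gap
            if dist < 1e-9:
                dist = 1e-9
            scale = max(scale, need / dist)
    return {sib: (x * scale, y * scale) for sib, (x, y) in pos.items()}


def compound_layout(pd_map: PDMap, config: LayoutConfig | None = None) -> PDMap:
    """Lay out a map preserving its nesting structure.

    Returns a new map; the input is not modified.  Leaf sizes are kept;
    container sizes are re-fitted around their children plus
    ``compartment_padding``.  The whole drawing is normalized so its
    top-left corner sits at the origin.
    """
    config = config or LayoutConfig()
    out = pd_map.copy()

    def _layout_level(siblings: list[str]) -> None:
        if not siblings:
            return
        for sib in siblings:  # bottom-up: size children first
            _layout_level(sorted(out.children_of(sib)))
            children = out.children_of(sib)
            if children:
                _fit_container(out, sib, children, config.compartment_padding)
        if len(siblings) == 1:
            g = out.glyphs[siblings[0]]
            _move_subtree(out, siblings[0], -g.bbox.x, -g.bbox.y)
            return
        graph = _sibling_graph(out, siblings)
        pos = nx.spring_layout(
            graph,
            k=config.ideal_edge_length,
            iterations=config.iterations,
            seed=config.seed,
            scale=config.ideal_edge_length * max(1.0, math.sqrt(len(siblings))),
        )
        pos = {sib: (float(x), float(y)) for sib, (x, y) in pos.items()}
        pos = _spread(out, siblings, pos, gap=config.compartment_padding)
        for sib in siblings:
            g = out.glyphs[sib]
            cx, cy = pos[sib]
            _move_subtree(out, sib, cx - g.bbox.cx, cy - g.bbox.cy)

    roots = sorted(out.roots())
    _layout_level(roots)
    # normalize to the origin
    if out.glyphs:
        min_x = min(g.bbox.x for g in out)
        min_y = min(g.bbox.y for g in out)
        for root in roots:
            _move_subtree(out, root, -min_x, -min_y)
    return out


def _move_subtree(pd_map: PDMap, gid: str, dx: float, dy: float) -> None:
    stack = [gid]
    while stack:
        cur = stack.pop()
        bb = pd_map.glyphs[cur].bbox
        pd_map.glyphs[cur].bbox = BBox(x=bb.x + dx, y=bb.y + dy, w=bb.w, h=bb.h)
        stack.extend(pd_map.children_of(cur))


def _fit_container(pd_map: PDMap, gid: str, children: frozenset[str], padding: float) -> None:
    boxes = [pd_map.glyphs[c].bbox for c in children]
    min_x = min(b.x for b in boxes) - padding
    min_y = min(b.y for b in boxes) - padding
    max_x = max(b.x + b.w for b in boxes) + padding
    max_y = max(b.y + b.h for b in boxes) + padding
    pd_map.glyphs[gid].bbox = BBox(x=min_x, y=min_y, w=max_x - min_x, h=max_y - min_y)


def containment_check(pd_map: PDMap, tol: float = 1e-6) -> list[tuple[str, str]]:
    """List every (child, parent) pair whose bboxes violate containment."""
    violations = []
    for glyph in pd_map:
        if glyph.parent_id is None:
            continue
        parent = pd_map.glyphs[glyph.parent_id]
        if not parent.bbox.contains(glyph.bbox, tol=tol):
            violations.append((glyph.id, glyph.parent_id))
    return violations


# ---------------------------------------------------------------------------
# SVG export
# ---------------------------------------------------------------------------

from lxml import etree  # noqa: E402

SVG_NS = "http://www.w3.org/2000/svg"

_ARROW_STYLE = {
    "consumption": None,
    "production": "filled",
    "catalysis": "circle",
    "stimulation": "open",
    "necessary stimulation": "open",
    "modulation": "diamond",
    "inhibition": "bar",
    "logic arc": None,
    "equivalence arc": None,
}

_FILL = {
    "compartment": "none",
    "complex": "#e8e8f8",
    "macromolecule": "#d2eadc",
    "simple chemical": "#fdf2cc",
    "nucleic acid feature": "#d9e6f2",
}


def _svg_shape(parent: etree._Element, glyph_class: str, bb: BBox) -> None:
    fill = _FILL.get(glyph_class, "#f5f5f5")
    if glyph_class == "simple chemical":
        etree.SubElement(parent, f"{{{SVG_NS}}}circle", cx=str(bb.cx), cy=str(bb.cy),
                         r=str(max(bb.w, bb.h) / 2 or 10.0), fill=fill, stroke="black")
    elif glyph_class == "complex":
        cut = min(bb.w, bb.h) / 5.0
        points = [
            (bb.x + cut, bb.y), (bb.x + bb.w - cut, bb.y), (bb.x + bb.w, bb.y + cut),
            (bb.x + bb.w, bb.y + bb.h - cut), (bb.x + bb.w - cut, bb.y + bb.h),
            (bb.x + cut, bb.y + bb.h), (bb.x, bb.y + bb.h - cut), (bb.x, bb.y + cut),
        ]
        etree.SubElement(parent, f"{{{SVG_NS}}}polygon",
                         points=" ".join(f"{x},{y}" for x, y in points),
                         fill=fill, stroke="black")
    else:
        attrs = {"x": str(bb.x), "y": str(bb.y), "width": str(bb.w), "height": str(bb.h),
                 "fill": fill, "stroke": "black"}
        if glyph_class == "macromolecule":
            attrs["rx"] = str(min(10.0, bb.h / 4 if bb.h else 10.0))
        if glyph_class == "compartment":
            attrs.update({"rx": "15", "stroke-width": "3"})
        etree.SubElement(parent, f"{{{SVG_NS}}}rect", attrs)


def export_svg(pd_map: PDMap, path: str) -> str:
    """Render a map as SVG 1.1 and write it to ``path``.

    Glyph shapes approximate PD notation: rounded rectangles for
    macromolecules, circles for simple chemicals, squares for process
    nodes, thick rounded rectangles for compartments, cut-corner
    rectangles for complexes.  Arcs are paths with class-distinct
    arrowheads.  Returns the SVG text.
    """
    if pd_map.glyphs:
        min_x = min(g.bbox.x for g in pd_map) - 10
        min_y = min(g.bbox.y for g in pd_map) - 10
        max_x = max(g.bbox.x + g.bbox.w for g in pd_map) + 10
        max_y = max(g.bbox.y + g.bbox.h for g in pd_map) + 10
    else:
        min_x = min_y = 0.0
        max_x = max_y = 10.0
    root = etree.Element(f"{{{SVG_NS}}}svg", nsmap={None: SVG_NS}, version="1.1",
                         width=str(max_x - min_x), height=str(max_y - min_y),
                         viewBox=f"{min_x} {min_y} {max_x - min_x} {max_y - min_y}")
    defs = etree.SubElement(root, f"{{{SVG_NS}}}defs")
    for name, shape in (("filled", "M0,0 L10,5 L0,10 z"), ("open", "M0,0 L10,5 L0,10"),
                        ("diamond", "M0,5 L5,0 L10,5 L5,10 z"), ("bar", "M8,0 L8,10"),
                        ("circle", "M2,5 a3,3 0 1,0 6,0 a3,3 0 1,0 -6,0")):
        marker = etree.SubElement(defs, f"{{{SVG_NS}}}marker", id=f"arrow-{name}",
                                  markerWidth="12", markerHeight="12", refX="9", refY="5",
                                  orient="auto", markerUnits="userSpaceOnUse")
        fill = "black" if name in ("filled", "diamond") else "white"
        etree.SubElement(marker, f"{{{SVG_NS}}}path", d=shape, fill=fill, stroke="black")

    # containers behind their contents: parents first
    def _depth(gid: str) -> int:
        d, pid = 0, pd_map.glyphs[gid].parent_id
        while pid is not None:
            d, pid = d + 1, pd_map.glyphs[pid].parent_id
        return d

    for gid in sorted(pd_map.glyphs, key=_depth):
        glyph = pd_map.glyphs[gid]
        _svg_shape(root, glyph.glyph_class, glyph.bbox)
        if glyph.label:
            text = etree.SubElement(root, f"{{{SVG_NS}}}text", x=str(glyph.bbox.cx),
                                    y=str(glyph.bbox.cy), **{"text-anchor": "middle",
                                    "dominant-baseline": "middle", "font-size": "12"})
            text.text = glyph.label

    for arc in pd_map.arcs.values():
        src = pd_map.glyphs[arc.source_id].bbox
        tgt = pd_map.glyphs[arc.target_id].bbox
        attrs = {"d": f"M{src.cx},{src.cy} L{tgt.cx},{tgt.cy}",
                 "stroke": "black", "fill": "none"}
        style = _ARROW_STYLE.get(arc.arc_class)
        if style:
            attrs["marker-end"] = f"url(#arrow-{style})"
        if arc.arc_class == "logic arc":
            attrs["stroke-dasharray"] = "4 2"
        etree.SubElement(root, f"{{{SVG_NS}}}path", attrs)

    text = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return text
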