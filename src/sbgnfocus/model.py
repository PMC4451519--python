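"""Compound-graph data model for SBGN Process Description (PD) maps.

An SBGN-PD map is modelled as a *compound graph*: glyphs (nodes) may be
nested inside complexes or compartments, and arcs (edges) connect glyphs.
This module holds the containers (:class:`Glyph`, :class:`Arc`,
:class:`PDMap`) and the four primitive set operators the complexity-
management closures are written in terms of: :func:`descendants`,
:func:`ancestors`, :func:`select_by_class` and :func:`neighborhood`.

Conventions
-----------
* Coordinates use a top-left origin with y growing downward (SVG / SBGN-ML
  practice).
* Ports are resolved to their owning glyph at parse time; every operator
  here works on glyph ids only.
* Auxiliary glyphs (state variables, units of information) live on their
  owner's ``aux`` list and are invisible to all graph algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import UnknownGlyphError

# ---------------------------------------------------------------------------
# Class vocabularies
# ---------------------------------------------------------------------------

#: Process-node classes of SBGN-PD.  ``phenotype`` is deliberately *not*
#: here: it behaves as a process-like sink for adjacency but the closure
#: selectors treat it as a non-process.
PROCESS_CLASSES = frozenset(
    {"process", "omitted process", "uncertain process", "association", "dissociation"}
)

#: Entity pool node classes (the "!process" side of the selectors, minus
#: compartments/logic/phenotype which are non-process but not EPNs).
EPN_CLASSES = frozenset(
    {
        "macromolecule",
        "simple chemical",
        "nucleic acid feature",
        "unspecified entity",
        "perturbing agent",
        "source and sink",
        "complex",
    }
)

LOGIC_CLASSES = frozenset({"and", "or", "not"})

#: Every glyph class a PD map node may carry.
GLYPH_CLASSES = (
    PROCESS_CLASSES
    | EPN_CLASSES
    | LOGIC_CLASSES
    | frozenset({"compartment", "phenotype", "tag"})
)

#: Auxiliary decorations attached to an owner glyph, never map nodes.
AUX_CLASSES = frozenset({"state variable", "unit of information"})

#: Modulation-family arc classes (the "effector" role).
EFFECTOR_ARC_CLASSES = frozenset(
    {"modulation", "stimulation", "catalysis", "inhibition", "necessary stimulation"}
)

ARC_CLASSES = EFFECTOR_ARC_CLASSES | frozenset(
    {"consumption", "production", "logic arc", "equivalence arc"}
)

#: Arc classes ignored by the closure algorithms (carried through I/O only).
NON_ADJACENCY_ARC_CLASSES = frozenset({"equivalence arc"})


def is_process(glyph_class: str) -> bool:
    """True for the five PD process-node classes."""
    return glyph_class in PROCESS_CLASSES


def is_epn(glyph_class: str) -> bool:
    """True for entity pool node classes (complex included)."""
    return glyph_class in EPN_CLASSES


def is_logic(glyph_class: str) -> bool:
    return glyph_class in LOGIC_CLASSES


def is_effector_arc(arc_class: str) -> bool:
    """True for the modulation family (catalysis, stimulation, ...)."""
    return arc_class in EFFECTOR_ARC_CLASSES


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class BBox:
    """Axis-aligned bounding box, top-left origin, w/h non-negative."""

    x: float = 0.0
    y: float = 0.0
    w: float = 0.0
    h: float = 0.0

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise ValueError(f"bbox w/h must be non-negative, got {self.w}x{self.h}")

    @property
    def cx(self) -> float:
        return self.x + self.w / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.h / 2.0

    def contains(self, other: "BBox", tol: float = 1e-9) -> bool:
        return (
            other.x >= self.x - tol
            and other.y >= self.y - tol
            and other.x + other.w <= self.x + self.w + tol
            and other.y + other.h <= self.y + self.h + tol
        )


@dataclass
class AuxGlyph:
    """A state variable or unit of information decorating an owner glyph."""

    id: str
    aux_class: str
    label: str = ""
    bbox: Optional[BBox] = None


@dataclass
class Port:
    """A connection anchor owned by a glyph (cosmetic after parsing)."""

    id: str
    owner_glyph_id: str
    x: float = 0.0
    y: float = 0.0


@dataclass
class Glyph:
    """One SBGN-PD node: EPN, process, complex, compartment, logic op, ..."""

    id: str
    glyph_class: str
    label: str = ""
    parent_id: Optional[str] = None
    bbox: BBox = field(default_factory=BBox)
    aux: list[AuxGlyph] = field(default_factory=list)
    compartment_ref: Optional[str] = None  # as read from SBGN-ML, informational
    extra: dict[str, str] = field(default_factory=dict)  # unknown XML attributes

    def __post_init__(self) -> None:
        if self.glyph_class not in GLYPH_CLASSES:
            raise ValueError(f"unknown glyph class {self.glyph_class!r} on {self.id!r}")


@dataclass
class Arc:
    """One SBGN-PD edge with endpoints resolved to glyph ids."""

    id: str
    arc_class: str
    source_id: str
    target_id: str
    source_port: Optional[str] = None  # original port ids, for lossless re-emit
    target_port: Optional[str] = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arc_class not in ARC_CLASSES:
            raise ValueError(f"unknown arc class {self.arc_class!r} on {self.id!r}")


class NodeGroup(frozenset):
    """An order-irrelevant set of glyph ids; input/output of all closures."""

    def __new__(cls, ids: Iterable[str] = ()) -> "NodeGroup":
        return super().__new__(cls, ids)

    def __repr__(self) -> str:  # stable, readable in test failures
        return f"NodeGroup({sorted(self)!r})"


class PDMap:
    """A whole PD map: glyph table, arc table, ports, nesting index.

    The parent relation (``Glyph.parent_id``) must form a forest; the
    children index is maintained as its exact inverse.
    """

    def __init__(self, map_id: str = "map1") -> None:
        self.map_id = map_id
        self.glyphs: dict[str, Glyph] = {}
        self.arcs: dict[str, Arc] = {}
        self.ports: dict[str, Port] = {}
        self._children: dict[str, set[str]] = {}
        self._adjacency: dict[str, set[str]] | None = None  # arc-id cache

    # -- construction -------------------------------------------------------

    def add_glyph(self, glyph: Glyph) -> Glyph:
        if glyph.id in self.glyphs:
            raise ValueError(f"duplicate glyph id {glyph.id!r}")
        self.glyphs[glyph.id] = glyph
        self._children.setdefault(glyph.id, set())
        if glyph.parent_id is not None:
            self._children.setdefault(glyph.parent_id, set()).add(glyph.id)
        self._adjacency = None
        return glyph

    def add_arc(self, arc: Arc) -> Arc:
        if arc.id in self.arcs:
            raise ValueError(f"duplicate arc id {arc.id!r}")
        self.arcs[arc.id] = arc
        self._adjacency = None
        return arc

    def add_port(self, port: Port) -> Port:
        if port.id in self.ports:
            raise ValueError(f"duplicate port id {port.id!r}")
        self.ports[port.id] = port
        return port

    def set_parent(self, glyph_id: str, parent_id: Optional[str]) -> None:
        glyph = self.glyphs[glyph_id]
        if glyph.parent_id is not None:
            self._children[glyph.parent_id].discard(glyph_id)
        glyph.parent_id = parent_id
        if parent_id is not None:
            self._children.setdefault(parent_id, set()).add(glyph_id)

    # -- queries -------------------------------------------------------------

    def __contains__(self, glyph_id: str) -> bool:
        return glyph_id in self.glyphs

    def __len__(self) -> int:
        return len(self.glyphs)

    def __iter__(self) -> Iterator[Glyph]:
        return iter(self.glyphs.values())

    def children_of(self, glyph_id: str) -> frozenset[str]:
        return frozenset(self._children.get(glyph_id, ()))

    def parent_of(self, glyph_id: str) -> Optional[str]:
        return self.glyphs[glyph_id].parent_id

    def roots(self) -> list[str]:
        return [g.id for g in self.glyphs.values() if g.parent_id is None]

    def all_nodes(self) -> NodeGroup:
        return NodeGroup(self.glyphs)

    def nesting_depth(self) -> int:
        """Longest root-to-leaf chain length in the containment forest."""
        depth: dict[str, int] = {}

        def _d(gid: str) -> int:
            if gid not in depth:
                pid = self.glyphs[gid].parent_id
                depth[gid] = 1 if pid is None else _d(pid) + 1
            return depth[gid]

        return max((_d(g) for g in self.glyphs), default=0)

    def arcs_touching(self, glyph_id: str) -> frozenset[str]:
        """Ids of non-equivalence arcs with ``glyph_id`` as an endpoint."""
        if self._adjacency is None:
            adj: dict[str, set[str]] = {gid: set() for gid in self.glyphs}
            for arc in self.arcs.values():
                if arc.arc_class in NON_ADJACENCY_ARC_CLASSES:
                    continue
                adj.setdefault(arc.source_id, set()).add(arc.id)
                adj.setdefault(arc.target_id, set()).add(arc.id)
            self._adjacency = adj
        return frozenset(self._adjacency.get(glyph_id, ()))

    def check_ids(self, group: Iterable[str]) -> NodeGroup:
        """Validate a node group against this map, returning it as NodeGroup."""
        group = NodeGroup(group)
        for gid in group:
            if gid not in self.glyphs:
                raise UnknownGlyphError(f"glyph id {gid!r} not in map {self.map_id!r}")
        return group

    def copy(self) -> "PDMap":
        import copy as _copy

        new = PDMap(self.map_id)
        for g in self.glyphs.values():
            new.add_glyph(_copy.deepcopy(g))
        for a in self.arcs.values():
            new.add_arc(_copy.deepcopy(a))
        for p in self.ports.values():
            new.add_port(_copy.deepcopy(p))
        return new


# ---------------------------------------------------------------------------
# Primitive set operators
# ---------------------------------------------------------------------------


def descendants(pd_map: PDMap, group: Iterable[str]) -> NodeGroup:
    """Transitive closure of the child relation over ``group``.

    Group members themselves are *not* included; callers union explicitly,
    mirroring the closure pseudocode (``nodeGroup ∪ nodeGroup.descendants()``).
    """
    group = pd_map.check_ids(group)
    out: set[str] = set()
    stack = list(group)
    while stack:
        for child in pd_map.children_of(stack.pop()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return NodeGroup(out - group)


def ancestors(pd_map: PDMap, group: Iterable[str]) -> NodeGroup:
    """Transitive closure of the parent relation over ``group`` (group excluded).

    Covers multi-level nesting (complex-in-complex-in-compartment) in one
    call: the closure invariant "the parent node should also be included"
    must hold recursively.
    """
    group = pd_map.check_ids(group)
    out: set[str] = set()
    for gid in group:
        pid = pd_map.parent_of(gid)
        while pid is not None and pid not in out:
            out.add(pid)
            pid = pd_map.parent_of(pid)
    return NodeGroup(out - group)


SELECTORS = ("process", "not-process", "complex")


def select_by_class(pd_map: PDMap, group: Iterable[str], selector: str) -> NodeGroup:
    """Filter a group by class: ``process``, ``not-process`` or ``complex``.

    ``not-process`` keeps everything :func:`is_process` rejects, so
    compartments, logic operators and phenotypes count as non-processes.
    """
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}; expected one of {SELECTORS}")
    group = pd_map.check_ids(group)
    if selector == "process":
        keep = lambda c: is_process(c)  # noqa: E731
    elif selector == "not-process":
        keep = lambda c: not is_process(c)  # noqa: E731
    else:
        keep = lambda c: c == "complex"  # noqa: E731
    return NodeGroup(g for g in group if keep(pd_map.glyphs[g].glyph_class))


def neighborhood(
    pd_map: PDMap, group: Iterable[str], class_filter: Optional[str] = None
) -> NodeGroup:
    """All glyphs connected to a group member by any arc, either direction.

    Group members themselves are excluded.  Logic arcs count as adjacency;
    equivalence arcs do not.  ``class_filter`` applies one of the
    :data:`SELECTORS` to the result.
    """
    group = pd_map.check_ids(group)
    out: set[str] = set()
    for gid in group:
        for arc_id in pd_map.arcs_touching(gid):
            arc = pd_map.arcs[arc_id]
            other = arc.target_id if arc.source_id == gid else arc.source_id
            out.add(other)
    result = NodeGroup(out - group)
    if class_filter is not None:
        result = select_by_class(pd_map, result, class_filter)
    return result
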