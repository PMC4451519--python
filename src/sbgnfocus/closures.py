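"""Domain-aware complexity management for SBGN-PD maps.

Generic graph filtering (hide these nodes, keep those) almost never yields
a valid process description map: arcs dangle, complexes lose members,
processes lose substrates.  The operations here instead *expand* a user's
node selection to the minimal sub-map that keeps five invariants intact:

1. every selected node is shown;
2. every process an initially selected EPN participates in is shown;
3. every substrate, product and effector of a selected (or invariant-2
   pulled) process is shown;
4. the parent chain (complexes, compartments) of every shown node is shown;
5. every member of a shown complex is shown, transitively.

``expand_nodes`` is the focus closure ("Show Selected");
``hide_selected`` composes it twice — expand the selection, then expand
its complement — so that hiding a node really removes it instead of being
re-pulled by the complement's expansion.

The closure is deliberately a *single pass*, not a fixpoint: iterating it
would flood to the whole connected component and defeat the point of a
minimal sub-map.  Re-applying ``expand_nodes`` to its own output may
therefore grow the set further; that is documented, intended behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import EmptySelectionError, ValidationError
from .model import (
    Arc,
    NodeGroup,
    PDMap,
    ancestors,
    descendants,
    is_epn,
    is_process,
    neighborhood,
    select_by_class,
)

# number of closure passes performed by the last expand_nodes call;
# exposed so tests can verify the single-pass contract by instrumentation.
_EXPAND_PASSES = {"count": 0}


@dataclass(frozen=True)
class VisibilityState:
    """Shown/hidden split of a map: the product of Show/Hide Selected.

    ``shown_arcs`` is derived state — an arc is shown iff both endpoint
    glyphs are shown; arcs are never independently selectable.
    """

    shown_nodes: NodeGroup
    shown_arcs: frozenset[str]
    warning: Optional[str] = None

    @property
    def empty(self) -> bool:
        return not self.shown_nodes


@dataclass
class InvariantReport:
    """Pass/fail result per closure invariant (indexed 1-5)."""

    results: list[tuple[int, bool, frozenset[str]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.results)

    def failures(self) -> list[tuple[int, frozenset[str]]]:
        return [(i, bad) for i, passed, bad in self.results if not passed]

    def __str__(self) -> str:
        lines = []
        for i, passed, bad in self.results:
            status = "pass" if passed else f"FAIL ({', '.join(sorted(bad))})"
            lines.append(f"invariant {i}: {status}")
        return "\n".join(lines)


def _arcs_between(pd_map: PDMap, shown: NodeGroup) -> frozenset[str]:
    return frozenset(
        a.id
        for a in pd_map.arcs.values()
        if a.source_id in shown and a.target_id in shown
    )


def expand_nodes(pd_map: PDMap, group: Iterable[str]) -> NodeGroup:
    """Expand a node group to the minimal valid sub-map node set.

    Straight-line execution, in order:

    1. union the descendants of the group (complex members);
    2. union the ancestors (parent complexes and compartments);
    3. union the descendants of every complex now in the group;
    4-5. split the group into processes and non-processes;
    6. ``neighborProcesses`` = processes adjacent to the non-processes;
    7. union the neighbors of in-group processes, ``neighborProcesses``
       themselves, and the neighbors of ``neighborProcesses``;
    8. union ancestors again;
    9. union complex descendants again.

    One pass only — see the module docstring.  An empty group expands to
    an empty group.
    """
    node_group = pd_map.check_ids(group)
    _EXPAND_PASSES["count"] += 1
    if not node_group:
        return NodeGroup()

    node_group |= descendants(pd_map, node_group)                          # 1
    node_group |= ancestors(pd_map, node_group)                            # 2
    node_group |= descendants(pd_map, select_by_class(pd_map, node_group, "complex"))  # 3
    processes = select_by_class(pd_map, node_group, "process")             # 4
    non_processes = select_by_class(pd_map, node_group, "not-process")     # 5
    neighbor_processes = neighborhood(pd_map, non_processes, "process")    # 6
    node_group |= (                                                        # 7
        neighborhood(pd_map, processes)
        | neighbor_processes
        | neighborhood(pd_map, neighbor_processes)
    )
    node_group |= ancestors(pd_map, node_group)                            # 8
    node_group |= descendants(pd_map, select_by_class(pd_map, node_group, "complex"))  # 9
    return NodeGroup(node_group)                                           # 10


def show_selected(pd_map: PDMap, group: Iterable[str]) -> VisibilityState:
    """Focus on a node group: show its closure, hide everything else."""
    node_group = pd_map.check_ids(group)
    if not node_group:
        raise EmptySelectionError("select at least one node to focus on")
    shown = expand_nodes(pd_map, node_group)
    return VisibilityState(shown_nodes=shown, shown_arcs=_arcs_between(pd_map, shown))


def expand_remaining_nodes(
    pd_map: PDMap, group: Iterable[str], all_elems: Optional[Iterable[str]] = None
) -> NodeGroup:
    """Closure of the complement of a (first expanded) node group.

    Expanding only the raw complement would pull hidden nodes straight
    back in — on a modification chain, hiding the native state would hide
    nothing at all.  Expanding the *selection* first, then taking the
    complement within ``all_elems`` (the visible universe) and expanding
    that, yields the set that may stay on screen.  The result can still
    intersect the original selection (e.g. a shared compartment); that is
    intended.
    """
    node_group = pd_map.check_ids(group)
    universe = pd_map.all_nodes() if all_elems is None else pd_map.check_ids(all_elems)
    expanded = expand_nodes(pd_map, node_group)
    remaining = NodeGroup(universe - expanded)
    return expand_nodes(pd_map, remaining)


def hide_selected(
    pd_map: PDMap, group: Iterable[str], all_elems: Optional[Iterable[str]] = None
) -> VisibilityState:
    """Hide a node group from the visible universe ``all_elems``.

    ``all_elems`` defaults to all map nodes; passing the previous state's
    ``shown_nodes`` makes successive hides compose.  An empty result is
    legal (a blank canvas) and flagged with a warning rather than raised.
    """
    node_group = pd_map.check_ids(group)
    universe = pd_map.all_nodes() if all_elems is None else pd_map.check_ids(all_elems)
    shown = NodeGroup(expand_remaining_nodes(pd_map, node_group, universe) & universe)
    warning = None
    if not shown:
        warning = "hide operation left no visible nodes"
    return VisibilityState(
        shown_nodes=shown, shown_arcs=_arcs_between(pd_map, shown), warning=warning
    )


# ---------------------------------------------------------------------------
# Invariant checker
# ---------------------------------------------------------------------------


def _participants(pd_map: PDMap, process_id: str) -> NodeGroup:
    """Substrates, products and effectors (incl. logic inputs) of a process."""
    return neighborhood(pd_map, NodeGroup({process_id}))


def invariant3_trigger_set(pd_map: PDMap, initial_selection: NodeGroup) -> NodeGroup:
    """Processes whose full participant set invariant 3 demands.

    These are the initially selected processes plus the processes adjacent
    to the selection's non-process closure after the descendant/ancestor/
    member steps — exactly the processes the focus closure treats this
    way, not processes that become visible only as parents' or members'
    neighbors.
    """
    if not initial_selection:
        return NodeGroup()
    grown = NodeGroup(initial_selection)
    grown |= descendants(pd_map, grown)
    grown |= ancestors(pd_map, grown)
    grown |= descendants(pd_map, select_by_class(pd_map, grown, "complex"))
    selected_processes = select_by_class(pd_map, grown, "process")
    non_processes = select_by_class(pd_map, grown, "not-process")
    return NodeGroup(selected_processes | neighborhood(pd_map, non_processes, "process"))


def check_invariants(
    pd_map: PDMap, initial_selection: Iterable[str], state: VisibilityState
) -> InvariantReport:
    """Check the five closure invariants of a visibility state.

    Reports per invariant; never raises.  Dangling arcs (one endpoint
    hidden) are reported under invariant 3, naming the hidden endpoint.
    """
    selection = pd_map.check_ids(initial_selection)
    shown = pd_map.check_ids(state.shown_nodes)
    report = InvariantReport()

    # 1. every selected node is shown
    bad1 = frozenset(selection - shown)
    report.results.append((1, not bad1, bad1))

    # 2. every process an initially selected EPN touches is shown
    bad2: set[str] = set()
    for gid in selection:
        if is_epn(pd_map.glyphs[gid].glyph_class):
            bad2 |= neighborhood(pd_map, NodeGroup({gid}), "process") - shown
    report.results.append((2, not bad2, frozenset(bad2)))

    # 3. trigger processes keep all substrates/products/effectors; and no
    # shown arc (derived or explicit) may dangle
    bad3: set[str] = set()
    for pid in invariant3_trigger_set(pd_map, selection):
        if pid in shown:
            bad3 |= _participants(pd_map, pid) - shown
    for arc_id in state.shown_arcs:
        arc = pd_map.arcs[arc_id]
        for endpoint in (arc.source_id, arc.target_id):
            if endpoint not in shown:
                bad3.add(endpoint)
    report.results.append((3, not bad3, frozenset(bad3)))

    # 4. ancestor-closed
    bad4 = frozenset(ancestors(pd_map, shown) - shown)
    report.results.append((4, not bad4, bad4))

    # 5. complex-complete
    bad5 = frozenset(
        descendants(pd_map, select_by_class(pd_map, shown, "complex")) - shown
    )
    report.results.append((5, not bad5, bad5))
    return report


def induced_submap(pd_map: PDMap, state: VisibilityState) -> PDMap:
    """Restrict a map to a visibility state's shown nodes and arcs.

    Requires the state to be ancestor-closed so no parent link can point
    at a hidden glyph.  The result is a standalone, structurally valid
    PDMap that can be written back to SBGN-ML.
    """
    shown = pd_map.check_ids(state.shown_nodes)
    missing_parents = ancestors(pd_map, shown) - shown
    if missing_parents:
        raise ValidationError(
            "visibility state is not ancestor-closed; hidden ancestors: "
            + ", ".join(sorted(missing_parents))
        )
    import copy as _copy

    sub = PDMap(pd_map.map_id)
    for gid, glyph in pd_map.glyphs.items():
        if gid in shown:
            sub.add_glyph(_copy.deepcopy(glyph))
    for arc_id, arc in pd_map.arcs.items():
        if arc_id in state.shown_arcs and arc.source_id in shown and arc.target_id in shown:
            sub.add_arc(_copy.deepcopy(arc))
    for port in pd_map.ports.values():
        if port.owner_glyph_id in shown:
            sub.add_port(_copy.deepcopy(port))
    return sub
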