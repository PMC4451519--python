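"""Independent naive oracles for the closure algorithms.

Deliberately written with plain dict/set scans over the map tables —
no reuse of the package's set operators — so that agreement with the
optimized implementation is a genuine dual-implementation check.
"""

from __future__ import annotations

from sbgnfocus.model import PDMap

PROCESS = {"process", "omitted process", "uncertain process", "association", "dissociation"}


def one_level_children(pd_map: PDMap, group: set[str]) -> set[str]:
    return {g.id for g in pd_map.glyphs.values() if g.parent_id in group}


def naive_descendants(pd_map: PDMap, group: set[str]) -> set[str]:
    """Iterated one-level-children fixpoint, group excluded."""
    acc = set(group)
    while True:
        nxt = acc | one_level_children(pd_map, acc)
        if nxt == acc:
            return acc - set(group)
        acc = nxt


def naive_ancestors(pd_map: PDMap, group: set[str]) -> set[str]:
    """Iterated one-level-parent fixpoint, group excluded."""
    acc = set(group)
    while True:
        nxt = acc | {
            pd_map.glyphs[g].parent_id
            for g in acc
            if pd_map.glyphs[g].parent_id is not None
        }
        if nxt == acc:
            return acc - set(group)
        acc = nxt


def naive_neighborhood(pd_map: PDMap, group: set[str], selector: str | None = None) -> set[str]:
    """Scan of all non-equivalence arcs touching the group."""
    out: set[str] = set()
    for arc in pd_map.arcs.values():
        if arc.arc_class == "equivalence arc":
            continue
        if arc.source_id in group:
            out.add(arc.target_id)
        if arc.target_id in group:
            out.add(arc.source_id)
    out -= set(group)
    if selector == "process":
        out = {g for g in out if pd_map.glyphs[g].glyph_class in PROCESS}
    return out


def naive_expand(pd_map: PDMap, group: set[str]) -> set[str]:
    """The ten pseudocode lines as naive set comprehensions, once, in order."""
    ng = set(group)
    if not ng:
        return ng
    ng = ng | naive_descendants(pd_map, ng)                                   # 1
    ng = ng | naive_ancestors(pd_map, ng)                                     # 2
    complexes = {g for g in ng if pd_map.glyphs[g].glyph_class == "complex"}
    ng = ng | naive_descendants(pd_map, complexes)                            # 3
    processes = {g for g in ng if pd_map.glyphs[g].glyph_class in PROCESS}    # 4
    non_processes = {g for g in ng if pd_map.glyphs[g].glyph_class not in PROCESS}  # 5
    neighbor_processes = naive_neighborhood(pd_map, non_processes, "process")  # 6
    ng = (                                                                    # 7
        ng
        | naive_neighborhood(pd_map, processes)
        | neighbor_processes
        | naive_neighborhood(pd_map, neighbor_processes)
    )
    ng = ng | naive_ancestors(pd_map, ng)                                     # 8
    complexes = {g for g in ng if pd_map.glyphs[g].glyph_class == "complex"}
    ng = ng | naive_descendants(pd_map, complexes)                            # 9
    return ng                                                                 # 10
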