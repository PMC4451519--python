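# sbgnfocus

Complexity management for SBGN Process Description (SBGN-PD) maps:
model a pathway map as a compound graph, and focus on or hide node
groups through domain-aware closures that always yield valid, complete
sub-maps — no dangling arcs, no complexes missing members, no processes
missing substrates.

Intended for computational biologists and tool builders who work with
pathway maps in SBGN-ML and need scriptable "Show Selected" / "Hide
Selected" operations, plus the surrounding plumbing: SBGN-ML reading and
writing, structural validation, a seeded synthetic-map generator,
nesting-preserving layout and SVG export.

## The core algorithm

A PD map is a compound graph: entity pool nodes (EPNs) and process nodes
connected by consumption/production/modulation arcs, nested inside
complexes and compartments. For a user-selected node group *G*, the
focus closure computes the minimal super-set of *G* whose induced
sub-map is again a valid PD map:

```
ExpandNodes(G):
  G ← G ∪ G.descendants()                 # members of selected complexes
  G ← G ∪ G.ancestors()                   # parent complexes/compartments
  G ← G ∪ complexes(G).descendants()      # complex-completeness
  P ← processes(G);  N ← nonProcesses(G)
  Q ← N.neighborhood('process')           # processes the selection feeds
  G ← G ∪ P.neighborhood() ∪ Q ∪ Q.neighborhood()
  G ← G ∪ G.ancestors()
  G ← G ∪ complexes(G).descendants()
  return G
```

executed exactly once (iterating to a fixpoint would flood the whole
connected component). Hiding composes the closure twice — expand the
selection, then expand its complement within the visible universe —
because expanding only the raw complement would pull the hidden nodes
straight back in. Every emitted visibility state satisfies five
invariants (selection shown; an EPN's processes shown; a process's
substrates/products/effectors shown; parents shown; complex members
shown), checked by `check_invariants`. See `docs/methods.md` for the
full account.

## Worked example

Hide the native state of a phosphorylation chain. The packaged fixture
`fig4_like.sbgn` holds `RSK → RSK-p → RSK-pp` in one compartment, with
ERK catalyzing the first step:

```sh
$ sbgnfocus info fixtures/fig4_like.sbgn
map id: fig4_like
nodes: 7
arcs: 5
processes: 2
nesting depth: 2
  compartment: 1
  macromolecule: 4
  process: 2

$ sbgnfocus hide-selected fixtures/fig4_like.sbgn -s rsk --out sub.sbgn
selection 'rsk' -> rsk
shown: 4 nodes, 2 arcs; hidden: 3 nodes
```

Three nodes disappear: `rsk` itself, its process `p1` (a process may not
be drawn without its substrate) and `p1`'s catalyst `erk` (now attached
to nothing visible). The remaining sub-map — `rsk_p`, `p2`, `rsk_pp`
and the shared compartment — is a complete PD map; expanding only the
complement instead would have re-shown all 7 nodes and hidden nothing.

The same operations are available as a library:

```python
from sbgnfocus import fixture, hide_selected, induced_submap, write_file

m = fixture("fig4_like")
state = hide_selected(m, {"rsk"})
sorted(state.shown_nodes)        # ['cytosol', 'p2', 'rsk_p', 'rsk_pp']
write_file(induced_submap(m, state), "sub.sbgn")
```

Other subcommands: `validate`, `show-selected`, `gen` (seeded random
maps), `layout` (nesting-preserving), `export-svg`.

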