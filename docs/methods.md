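# Methods

## The problem

An SBGN Process Description (PD) map depicts state transitions of
molecular entities: entity pool nodes (EPNs — macromolecules, simple
chemicals, complexes, ...) are connected to process nodes by consumption,
production and modulation-family arcs, and may be nested inside complexes
and compartments to arbitrary depth. Generic graph filtering ("show only
these nodes") applied to such a map almost always produces something that
is no longer a valid PD map: arcs dangle, complexes lose the members that
define their identity, processes lose substrates so the drawing silently
asserts a different reaction.

`sbgnfocus` treats a PD map as a compound graph and reduces its
complexity only through closures that keep five invariants intact for a
node group *G* chosen to be shown (or hidden):

1. every node of *G* is shown;
2. for every EPN in *G*, every process it participates in is shown;
3. for every selected (or invariant-2 pulled) process, all of its
   substrates, products and effectors are shown;
4. the parent chain (complex or compartment) of every shown node is
   shown, transitively;
5. every member of a shown complex is shown, transitively.

## The focus closure

`expand_nodes(map, G)` computes the minimal node set whose induced
sub-map satisfies the invariants. It is a straight-line program over
four primitive operators — `descendants` (transitive child closure),
`ancestors` (transitive parent closure), `select_by_class`
(process / not-process / complex) and `neighborhood` (arc adjacency,
undirected, equivalence arcs excluded):

```
G ← G ∪ descendants(G)
G ← G ∪ ancestors(G)
G ← G ∪ descendants(complexes(G))
P  ← processes(G);  N ← non-processes(G)
Q  ← neighborhood(N) ∩ processes          # processes the selection feeds
G ← G ∪ neighborhood(P) ∪ Q ∪ neighborhood(Q)
G ← G ∪ ancestors(G)
G ← G ∪ descendants(complexes(G))
```

Two design points matter:

* **`ancestors`/`descendants` are transitive, not one-level.** Invariant
  4 must hold recursively: a member of a complex that sits inside
  another complex inside a compartment pulls in the whole chain in one
  call.
* **Single pass, deliberately not idempotent.** EPNs that enter the set
  as a process's participants would, on a second pass, pull in *their*
  other processes; iterating to a fixpoint floods the connected
  component and defeats the notion of a minimal sub-map. The
  implementation executes the lines once, in order; re-application may
  strictly grow the set, and the test suite asserts this happens on
  concrete maps rather than treating it as a defect.

`show_selected` wraps the closure in a `VisibilityState`: an arc is
shown iff both endpoints are shown (arcs are derived state, never
independently selectable).

## The hide closure

Hiding by expanding the complement does not work: on a modification
chain (native → phosphorylated → bis-phosphorylated), hiding the native
state and expanding the rest re-pulls the native state through its
process — nothing gets hidden. `hide_selected` therefore composes the
closure twice:

```
shown  = expand_nodes(all_elems − expand_nodes(G))
hidden = all_elems − shown
```

`all_elems` is the currently visible universe, so successive hides
compose; an empty result is legal (blank canvas) and reported with a
warning flag rather than an error. The shown set may still intersect
the closure of *G* — a shared compartment typically survives — which is
correct: the compartment is context for the remaining nodes.

### Invariant-3 trigger set

Invariant 3 is checked for the initially selected processes plus the
processes adjacent to the selection's non-process closure after the
descendant/ancestor/member steps — exactly the processes the closure
expands fully. Processes that become visible only as parents' or
members' neighbors are *not* required to have all participants visible;
requiring that would be the fixpoint semantics rejected above.

### Monotonicity convention

The primitive operators exclude the query group from their result
(callers union explicitly, mirroring the closure's `G ∪ op(G)` shape).
Under this convention the primitives are monotone modulo the group —
`op(G1) − G2 ⊆ op(G2)` for `G1 ⊆ G2` — while `expand_nodes` itself,
which always re-unions the group, is monotone outright and inflationary.

## SBGN-ML I/O

Reading and writing target the 0.2-era SBGN-ML dialect: complex
membership is encoded by XML nesting (which wins over `compartmentRef`
when both are present), compartment membership by `compartmentRef`,
ports are resolved to their owning glyph at parse time and treated as
cosmetic afterwards, and auxiliary glyphs (state variables, units of
information) are stored on their owner and invisible to the closures.
Unknown attributes are kept verbatim and re-emitted. Coordinates use a
top-left origin with y growing downward. Bounding boxes round-trip to
full float precision (`repr`-based formatting). Writing refuses maps
that fail structural validation, returning the validation report.

Equivalence arcs and tags are parsed and re-emitted but ignored by all
closure algorithms. Logic operators (and/or/not) count as non-processes
for the selectors but participate in adjacency, so a logic operator
wired to a process is pulled in like an effector EPN; a selected logic
operator does not recursively pull its upstream inputs — adjacency only.
Phenotype glyphs are accepted as targets of modulation-family arcs (they
are process-like sinks in PD notation) but are not process nodes for the
selectors; they enter sub-maps only via neighborhood.

## Synthetic maps

The generator (`generate_map`) emulates the structural features the
closures care about: compartments holding entities and processes,
root-level pools that may be complexes with members nested to a bounded
depth, processes with 1–2 substrates and products, and optional
modulation arcs whose effector is drawn from pools not already
participating in that process. Defaults: 1 compartment, 5 processes,
10 EPNs, complex probability 0.25, nesting depth ≤ 3, effector
probability 0.3 — small enough to read, rich enough to exercise every
closure step. Identical configs (seed included) produce byte-identical
SBGN-ML. Substrates and products are drawn from root-level pools only;
complex members are reached through the descendant steps, which is the
code path worth stressing.

What the generator does **not** emulate: reaction-type distributions of
real pathway databases, stoichiometry, clone markers, submap/tag
expansion, or logic-gate regulation (logic operators are covered by
hand-built tests instead). Passing the property suites therefore shows
the closures are correct on the compound-graph structure of PD maps,
not that any biological statement holds.

The named fixtures encode figure-style scenarios by topology; labels are
cosmetic analogs:

* `fig1_like` — four processes, two shared pools each participating in
  several of them, one complex: the map on which generic filtering of a
  two-pool selection dangles four arcs while the focus closure passes
  all invariants;
* `fig2_like` — a pool inside a complex inside a larger complex inside
  a compartment: multi-level ancestors and complex-completeness;
* `fig4_like` — a linear modification chain in one compartment: the map
  on which naive complement-expansion hides nothing while the two-stage
  hide removes the selected state, its process and that process's
  effector;
* `minimal_process` — one process, one substrate, one product.

## Layout and SVG

The layout contract is geometric: after `compound_layout`, every child
bbox lies inside its parent inflated by `compartment_padding`
(default 20 map units) and sibling groups do not overlap. The algorithm
recurses bottom-up: each compound's children are laid out with a seeded
spring embedder (networkx `spring_layout`, default 50 iterations, ideal
edge length 120), sibling positions are rescaled until no two sibling
boxes can collide (pairwise half-diagonal separation, with a
deterministic sub-millimap jitter for coincident spring positions), and
the parent bbox is fitted around its children plus padding. Root nodes
are siblings of a virtual root, and the drawing is normalized to the
origin. Overlap between non-siblings is tolerated; visual polish is out
of scope. Identical (map, config) pairs give identical coordinates.

SVG export approximates PD shapes — rounded rectangles for
macromolecules, circles for simple chemicals, squares for processes,
thick rounded rectangles for compartments, cut-corner octagons for
complexes — with class-distinct arrowheads (filled for production, open
for stimulation, circle for catalysis, bar for inhibition, diamond for
modulation). One shape element per glyph, one path per arc; containers
are drawn before their contents.

## Numerical and degenerate-input choices

* Containment checks use a 1e-6 tolerance (absolute, map units);
  round-trip bbox comparison uses 1e-9.
* Empty selection: `expand_nodes` returns the empty group;
  `show_selected` raises (a GUI would prompt); `hide_selected` of the
  empty group keeps everything.
* Self-loop arcs and duplicate ids are rejected at validation; the
  validator reports, it never throws.
* Problem sizes in the test and acceptance sweeps: 100 maps of up to
  300 nodes (nesting depth ≤ 4) with 500 selections for oracle
  agreement, 200 (map, selection) pairs for the invariant suite, 100
  maps for round-trip, 50 for layout — sizes at which each sweep
  completes in seconds while covering every generator regime.

## Known limitations

* No BioPAX conversion, no CellDesigner/GraphML dialects, no
  stoichiometry or cardinality labels, no submap expansion semantics.
* A selected logic operator pulls only its adjacent nodes; whether it
  should pull its full upstream input cone is a modelling choice this
  package resolves as "adjacency only" and documents rather than
  asserts.
* The layout optimizes nothing beyond the containment contract; edge
  crossings and compactness are whatever the spring embedder produces.
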