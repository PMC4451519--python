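"""Synthetic SBGN-PD maps: seeded random generator, named fixtures and a
structural well-formedness checker.

The generator produces structurally valid PD maps (every process has at
least one substrate and one product, complexes are non-empty, nesting
respects the compartment/complex rules) so the closure algorithms can be
property-tested at any scale without external data.  The named fixtures
are small hand-built maps reproducing the topologies the focus/hide
walkthroughs are usually illustrated with: shared entities participating
in several processes, multi-level complex nesting inside a compartment,
and a linear modification chain.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .errors import ConfigError
from .model import (
    Arc,
    BBox,
    Glyph,
    PDMap,
    is_epn,
    is_logic,
    is_process,
)

_SIMPLE_EPN_CLASSES = (
    "macromolecule",
    "macromolecule",
    "simple chemical",
    "nucleic acid feature",
    "unspecified entity",
)
_PROCESS_CLASSES = ("process", "process", "process", "omitted process", "uncertain process")
_EFFECTOR_CLASSES = ("catalysis", "stimulation", "inhibition", "modulation")

#: Default node sizes by role (map units).
EPN_SIZE = (80.0, 40.0)
PROCESS_SIZE = (20.0, 20.0)


@dataclass(frozen=True)
class MapGenConfig:
    """Configuration of the random map generator.

    Identical configs (seed included) produce identical maps, hence
    byte-identical SBGN-ML.
    """

    n_compartments: int = 1
    n_processes: int = 5
    n_epns: int = 10
    complex_prob: float = 0.25
    max_nest_depth: int = 3
    effector_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compartments < 0:
            raise ConfigError("n_compartments must be >= 0")
        if self.n_processes < 1:
            raise ConfigError("n_processes must be >= 1")
        if self.n_epns < 2:
            raise ConfigError("n_epns must be >= 2 (a process needs a substrate and a product)")
        if not 0.0 <= self.complex_prob <= 1.0:
            raise ConfigError("complex_prob must be a probability")
        if not 0.0 <= self.effector_prob <= 1.0:
            raise ConfigError("effector_prob must be a probability")
        if self.max_nest_depth < 1:
            raise ConfigError("max_nest_depth must be >= 1")


def generate_map(config: MapGenConfig) -> PDMap:
    """Generate a structurally valid random PD map.

    Root-level entity pools (possibly complexes with nested members up to
    ``max_nest_depth``) are wired to processes by consumption/production
    arcs; effector arcs are added with probability ``effector_prob`` per
    process, drawn from pools not already participating in it.  Bounding
    boxes are placed uniformly at random in a canvas proportional to the
    node count (a deliberately poor layout for the layout module to fix).
    """
    rng = random.Random(config.seed)
    pd_map = PDMap(f"generated-{config.seed}")

    compartments = []
    for i in range(config.n_compartments):
        comp = pd_map.add_glyph(Glyph(id=f"k{i}", glyph_class="compartment", label=f"compartment {i}"))
        compartments.append(comp.id)

    def _compartment_or_none() -> str | None:
        if compartments and rng.random() < 0.8:
            return rng.choice(compartments)
        return None

    def _fill_complex(cx_id: str, depth: int) -> None:
        n_members = rng.randint(1, 3)
        for j in range(n_members):
            member_id = f"{cx_id}m{j}"
            nest = depth < config.max_nest_depth and rng.random() < config.complex_prob
            if nest:
                pd_map.add_glyph(
                    Glyph(id=member_id, glyph_class="complex", label=f"{member_id} cx", parent_id=cx_id)
                )
                _fill_complex(member_id, depth + 1)
            else:
                pd_map.add_glyph(
                    Glyph(
                        id=member_id,
                        glyph_class=rng.choice(_SIMPLE_EPN_CLASSES),
                        label=member_id,
                        parent_id=cx_id,
                    )
                )

    root_epns = []
    for i in range(config.n_epns):
        eid = f"e{i}"
        parent = _compartment_or_none()
        if rng.random() < config.complex_prob:
            pd_map.add_glyph(Glyph(id=eid, glyph_class="complex", label=f"{eid} cx", parent_id=parent))
            _fill_complex(eid, 2 if parent is not None else 1)
        else:
            pd_map.add_glyph(
                Glyph(id=eid, glyph_class=rng.choice(_SIMPLE_EPN_CLASSES), label=eid, parent_id=parent)
            )
        root_epns.append(eid)

    arc_counter = 0

    def _add_arc(arc_class: str, source: str, target: str) -> None:
        nonlocal arc_counter
        pd_map.add_arc(Arc(id=f"a{arc_counter}", arc_class=arc_class, source_id=source, target_id=target))
        arc_counter += 1

    for i in range(config.n_processes):
        pid = f"p{i}"
        pd_map.add_glyph(
            Glyph(id=pid, glyph_class=rng.choice(_PROCESS_CLASSES), parent_id=_compartment_or_none())
        )
        n_sub = rng.randint(1, min(2, len(root_epns) - 1))
        substrates = rng.sample(root_epns, n_sub)
        rest = [e for e in root_epns if e not in substrates]
        products = rng.sample(rest, rng.randint(1, min(2, len(rest))))
        for s in substrates:
            _add_arc("consumption", s, pid)
        for p in products:
            _add_arc("production", pid, p)
        if rng.random() < config.effector_prob:
            candidates = [e for e in root_epns if e not in substrates and e not in products]
            if candidates:
                _add_arc(rng.choice(_EFFECTOR_CLASSES), rng.choice(candidates), pid)

    _scatter_bboxes(pd_map, rng)
    return pd_map


def _scatter_bboxes(pd_map: PDMap, rng: random.Random) -> None:
    """Place every glyph uniformly at random on a canvas ~ node count."""
    side = 120.0 * max(2.0, math.sqrt(len(pd_map)))
    for glyph in pd_map:
        if is_process(glyph.glyph_class) or is_logic(glyph.glyph_class):
            w, h = PROCESS_SIZE
        else:
            w, h = EPN_SIZE
        glyph.bbox = BBox(
            x=round(rng.uniform(0, side), 3), y=round(rng.uniform(0, side), 3), w=w, h=h
        )


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("fig1_like", "fig2_like", "fig4_like", "minimal_process")


def fixture(name: str) -> PDMap:
    """Return a hand-built deterministic map for a named scenario.

    ``fig1_like``
        Four processes sharing two entities ("NBN"-analogs) that each
        participate in several of them, plus one complex ("MRN"-analog).
        The scenario where naive filtering of a selection leaves dangling
        references while the focus closure does not.
    ``fig2_like``
        Two-level complex nesting (a "myosin" pool inside a complex
        inside a larger "actin-myosin" complex) within a "muscle cytosol"
        compartment, with processes both inside and outside the closure
        of the canonical selection.
    ``fig4_like``
        A linear modification chain ("RSK" native → phospho → bis-phospho)
        in one compartment: the closure of a selection and the closure of
        its complement overlap on the shared compartment, which is what
        makes naive hiding show everything again.
    ``minimal_process``
        One process consuming one pool and producing another: 3 nodes,
        2 arcs.

    Topology is the contract; labels are cosmetic analogs.
    """
    builders = {
        "fig1_like": _fig1_like,
        "fig2_like": _fig2_like,
        "fig4_like": _fig4_like,
        "minimal_process": _minimal_process,
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    pd_map = builders[name]()
    _grid_bboxes(pd_map)
    return pd_map


def _grid_bboxes(pd_map: PDMap) -> None:
    """Deterministic non-random placement for fixtures (layout input)."""
    cols = max(1, math.ceil(math.sqrt(len(pd_map))))
    for i, glyph in enumerate(pd_map):
        if is_process(glyph.glyph_class) or is_logic(glyph.glyph_class):
            w, h = PROCESS_SIZE
        else:
            w, h = EPN_SIZE
        glyph.bbox = BBox(x=140.0 * (i % cols), y=90.0 * (i // cols), w=w, h=h)


def _minimal_process() -> PDMap:
    m = PDMap("minimal_process")
    m.add_glyph(Glyph(id="sub", glyph_class="macromolecule", label="substrate"))
    m.add_glyph(Glyph(id="prc", glyph_class="process"))
    m.add_glyph(Glyph(id="prd", glyph_class="macromolecule", label="product"))
    m.add_arc(Arc(id="a1", arc_class="consumption", source_id="sub", target_id="prc"))
    m.add_arc(Arc(id="a2", arc_class="production", source_id="prc", target_id="prd"))
    return m


def _fig1_like() -> PDMap:
    """Four processes, two shared pools, one complex.

    nbn1 participates in p1 and p2; nbn2 in p2 and p3; the complex mrn
    (members nbn_m, mre11, rad50) is produced by p2 (an association) and
    catalyzes p4.
    """
    m = PDMap("fig1_like")
    for gid, label in (("nbn1", "NBN"), ("nbn2", "NBN"), ("atm", "ATM"),
                       ("atm_p", "ATM-p"), ("chk", "CHK2"), ("chk_p", "CHK2-p")):
        m.add_glyph(Glyph(id=gid, glyph_class="macromolecule", label=label))
    m.add_glyph(Glyph(id="mrn", glyph_class="complex", label="MRN"))
    for gid, label in (("nbn_m", "NBN"), ("mre11", "MRE11"), ("rad50", "RAD50")):
        m.add_glyph(Glyph(id=gid, glyph_class="macromolecule", label=label, parent_id="mrn"))
    m.add_glyph(Glyph(id="p1", glyph_class="process"))
    m.add_glyph(Glyph(id="p2", glyph_class="association"))
    m.add_glyph(Glyph(id="p3", glyph_class="process"))
    m.add_glyph(Glyph(id="p4", glyph_class="process"))
    arcs = [
        ("a1", "consumption", "nbn1", "p1"),
        ("a2", "production", "p1", "atm_p"),
        ("a3", "consumption", "atm", "p1"),
        ("a4", "consumption", "nbn1", "p2"),
        ("a5", "consumption", "nbn2", "p2"),
        ("a6", "production", "p2", "mrn"),
        ("a7", "consumption", "nbn2", "p3"),
        ("a8", "production", "p3", "chk"),
        ("a9", "consumption", "chk", "p4"),
        ("a10", "production", "p4", "chk_p"),
        ("a11", "catalysis", "mrn", "p4"),
    ]
    for aid, cls, s, t in arcs:
        m.add_arc(Arc(id=aid, arc_class=cls, source_id=s, target_id=t))
    return m


def _fig2_like() -> PDMap:
    """Two-level complex nesting in a compartment, plus an unrelated branch.

    myosin_cx (member: myosin) sits inside actin_myosin, which sits in
    the muscle_cytosol compartment.  p1 consumes myosin_cx; p2 continues
    the chain; p3 is an unrelated process the focus closure must drop.
    """
    m = PDMap("fig2_like")
    m.add_glyph(Glyph(id="muscle_cytosol", glyph_class="compartment", label="muscle cytosol"))
    m.add_glyph(Glyph(id="actin_myosin", glyph_class="complex", label="actin-myosin",
                      parent_id="muscle_cytosol"))
    m.add_glyph(Glyph(id="myosin_cx", glyph_class="complex", label="myosin complex",
                      parent_id="actin_myosin"))
    m.add_glyph(Glyph(id="myosin", glyph_class="macromolecule", label="myosin",
                      parent_id="myosin_cx"))
    m.add_glyph(Glyph(id="actin", glyph_class="macromolecule", label="actin",
                      parent_id="actin_myosin"))
    for gid, label in (("e1", "intermediate"), ("e2", "end product"), ("enz", "enzyme"),
                       ("f1", "unrelated in"), ("f2", "unrelated out")):
        m.add_glyph(Glyph(id=gid, glyph_class="macromolecule", label=label,
                          parent_id="muscle_cytosol"))
    for pid in ("p1", "p2", "p3"):
        m.add_glyph(Glyph(id=pid, glyph_class="process", parent_id="muscle_cytosol"))
    arcs = [
        ("a1", "consumption", "myosin_cx", "p1"),
        ("a2", "production", "p1", "e1"),
        ("a3", "consumption", "e1", "p2"),
        ("a4", "production", "p2", "e2"),
        ("a5", "catalysis", "enz", "p2"),
        ("a6", "consumption", "f1", "p3"),
        ("a7", "production", "p3", "f2"),
    ]
    for aid, cls, s, t in arcs:
        m.add_arc(Arc(id=aid, arc_class=cls, source_id=s, target_id=t))
    return m


def _fig4_like() -> PDMap:
    """Linear modification chain sharing one compartment.

    rsk --p1(cat: erk)--> rsk_p --p2--> rsk_pp, all inside the cytosol.
    Hiding {rsk} must actually hide rsk, p1 and erk even though the
    complement's closure re-reaches rsk_p and the shared compartment.
    """
    m = PDMap("fig4_like")
    m.add_glyph(Glyph(id="cytosol", glyph_class="compartment", label="cytosol"))
    for gid, label in (("rsk", "RSK"), ("rsk_p", "RSK-p"), ("rsk_pp", "RSK-pp"),
                       ("erk", "ERK")):
        m.add_glyph(Glyph(id=gid, glyph_class="macromolecule", label=label, parent_id="cytosol"))
    for pid in ("p1", "p2"):
        m.add_glyph(Glyph(id=pid, glyph_class="process", parent_id="cytosol"))
    arcs = [
        ("a1", "consumption", "rsk", "p1"),
        ("a2", "production", "p1", "rsk_p"),
        ("a3", "catalysis", "erk", "p1"),
        ("a4", "consumption", "rsk_p", "p2"),
        ("a5", "production", "p2", "rsk_pp"),
    ]
    for aid, cls, s, t in arcs:
        m.add_arc(Arc(id=aid, arc_class=cls, source_id=s, target_id=t))
    return m


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------


@dataclass
class StructuralReport:
    """Pass/fail per structural well-formedness check (reports, never throws)."""

    results: list[tuple[str, bool, frozenset[str]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.results)

    def failures(self) -> list[tuple[str, frozenset[str]]]:
        return [(name, bad) for name, passed, bad in self.results if not passed]

    def __str__(self) -> str:
        lines = []
        for name, passed, bad in self.results:
            status = "pass" if passed else f"FAIL ({', '.join(sorted(bad))})"
            lines.append(f"{name}: {status}")
        return "\n".join(lines)


def _legal_endpoints(pd_map: PDMap, arc: Arc) -> bool:
    src = pd_map.glyphs[arc.source_id].glyph_class
    tgt = pd_map.glyphs[arc.target_id].glyph_class
    if arc.arc_class == "consumption":
        return is_epn(src) and is_process(tgt)
    if arc.arc_class == "production":
        return is_process(src) and is_epn(tgt)
    if arc.arc_class == "logic arc":
        return (is_epn(src) or is_logic(src)) and is_logic(tgt)
    if arc.arc_class == "equivalence arc":
        return True  # carried through I/O, ignored by closures
    # modulation family: phenotype accepted as a process-like sink
    return (is_epn(src) or is_logic(src)) and (is_process(tgt) or tgt == "phenotype")


def validate_structure(pd_map: PDMap) -> StructuralReport:
    """Check PD well-formedness of a map.

    Checks: unique ids with resolvable references and no self-loop arcs;
    the parent relation is an acyclic forest over complexes/compartments;
    compartments are never nested inside complexes or other compartments;
    arc endpoint classes are legal for the arc class; every process has
    at least one consumption and one production arc; complexes are
    non-empty.
    """
    report = StructuralReport()

    bad_ref: set[str] = set()
    for arc in pd_map.arcs.values():
        if arc.source_id not in pd_map.glyphs or arc.target_id not in pd_map.glyphs:
            bad_ref.add(arc.id)
        elif arc.source_id == arc.target_id:
            bad_ref.add(arc.id)
    for glyph in pd_map:
        if glyph.parent_id is not None and glyph.parent_id not in pd_map.glyphs:
            bad_ref.add(glyph.id)
    report.results.append(("references", not bad_ref, frozenset(bad_ref)))
    if bad_ref:
        return report  # remaining checks assume resolvable references

    cyclic: set[str] = set()
    state: dict[str, int] = {}  # 0 visiting, 1 done
    for gid in pd_map.glyphs:
        chain = []
        cur: str | None = gid
        while cur is not None and cur not in state:
            state[cur] = 0
            chain.append(cur)
            cur = pd_map.glyphs[cur].parent_id
            if cur is not None and state.get(cur) == 0:
                cyclic.update(chain + [cur])
                cur = None
        for c in chain:
            state[c] = 1
    report.results.append(("parent-forest-acyclic", not cyclic, frozenset(cyclic)))

    bad_parent: set[str] = set()
    for glyph in pd_map:
        if glyph.parent_id is None or glyph.id in cyclic:
            continue
        parent_class = pd_map.glyphs[glyph.parent_id].glyph_class
        if parent_class not in ("complex", "compartment"):
            bad_parent.add(glyph.id)
        elif glyph.glyph_class == "compartment":
            bad_parent.add(glyph.id)  # compartments are root containers
    report.results.append(("parent-classes", not bad_parent, frozenset(bad_parent)))

    bad_arc = frozenset(a.id for a in pd_map.arcs.values() if not _legal_endpoints(pd_map, a))
    report.results.append(("arc-roles", not bad_arc, bad_arc))

    incomplete: set[str] = set()
    for glyph in pd_map:
        if not is_process(glyph.glyph_class):
            continue
        classes = {pd_map.arcs[a].arc_class for a in pd_map.arcs_touching(glyph.id)}
        if "consumption" not in classes or "production" not in classes:
            incomplete.add(glyph.id)
    report.results.append(("process-completeness", not incomplete, frozenset(incomplete)))

    empty_cx = frozenset(
        g.id for g in pd_map if g.glyph_class == "complex" and not pd_map.children_of(g.id)
    )
    report.results.append(("complexes-nonempty", not empty_cx, empty_cx))
    return report
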