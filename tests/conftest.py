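import random
from pathlib import Path

import pytest

from sbgnfocus import MapGenConfig, NodeGroup, fixture, generate_map

FIXTURES_DIR = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture
def minimal_map():
    return fixture("minimal_process")


@pytest.fixture
def fig1_map():
    return fixture("fig1_like")


@pytest.fixture
def fig2_map():
    return fixture("fig2_like")


@pytest.fixture
def fig4_map():
    return fixture("fig4_like")


def random_config(rng: random.Random) -> MapGenConfig:
    """A varied but always-satisfiable generator config."""
    return MapGenConfig(
        n_compartments=rng.randint(0, 3),
        n_processes=rng.randint(1, 12),
        n_epns=rng.randint(2, 25),
        complex_prob=rng.choice([0.0, 0.2, 0.4, 0.6]),
        max_nest_depth=rng.randint(1, 4),
        effector_prob=rng.choice([0.0, 0.3, 0.7]),
        seed=rng.randrange(2**31),
    )


def random_maps(n: int, master_seed: int = 20240901):
    """Yield n (map, rng) pairs from varied seeded configs."""
    rng = random.Random(master_seed)
    for _ in range(n):
        yield generate_map(random_config(rng)), rng


def random_selection(pd_map, rng: random.Random, allow_empty: bool = False) -> NodeGroup:
    ids = sorted(pd_map.glyphs)
    lo = 0 if allow_empty else 1
    k = rng.randint(lo, max(lo, min(len(ids), 6)))
    return NodeGroup(rng.sample(ids, k))


def assert_isomorphic(a, b):
    """Structural equality of two PD maps: ids, classes, labels, parents,
    arcs and bboxes (within 1e-9)."""
    assert set(a.glyphs) == set(b.glyphs)
    assert set(a.arcs) == set(b.arcs)
    for gid, g in a.glyphs.items():
        h = b.glyphs[gid]
        assert g.glyph_class == h.glyph_class
        assert g.label == h.label
        assert g.parent_id == h.parent_id
        for attr in ("x", "y", "w", "h"):
            assert abs(getattr(g.bbox, attr) - getattr(h.bbox, attr)) < 1e-9
    for aid, arc in a.arcs.items():
        brc = b.arcs[aid]
        assert (arc.arc_class, arc.source_id, arc.target_id) == (
            brc.arc_class, brc.source_id, brc.target_id)
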