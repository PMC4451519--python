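"""Focus/hide closures: walkthrough examples, invariants, oracle agreement."""

import pytest

from sbgnfocus import (
    NodeGroup,
    VisibilityState,
    check_invariants,
    expand_nodes,
    expand_remaining_nodes,
    hide_selected,
    induced_submap,
    parse_sbgnml,
    show_selected,
    validate_structure,
    write_sbgnml,
)
from sbgnfocus.errors import EmptySelectionError, UnknownGlyphError, ValidationError

from conftest import assert_isomorphic, random_maps, random_selection
from oracle import naive_expand


class TestExpandNodes:
    def test_empty_group_stays_empty(self, fig2_map):
        assert expand_nodes(fig2_map, NodeGroup()) == NodeGroup()

    def test_unknown_id_raises(self, fig2_map):
        with pytest.raises(UnknownGlyphError, match="ghost"):
            expand_nodes(fig2_map, {"ghost"})

    def test_focus_walkthrough_on_nested_complex(self, fig2_map):
        """Selecting the myosin-containing complex and the process that
        consumes it pulls in: the member (children step), the enclosing
        complex and compartment (parents step), the sibling member of the
        enclosing complex (complex-completeness), and the process's
        product — and nothing from the unrelated branch."""
        got = expand_nodes(fig2_map, {"myosin_cx", "p1"})
        assert got == NodeGroup({
            "myosin_cx", "p1",            # selection
            "myosin",                     # children of selection
            "actin_myosin", "muscle_cytosol",  # ancestors, multi-level
            "actin",                      # member of pulled-in complex
            "e1",                         # product of selected process
        })
        for excluded in ("p2", "p3", "e2", "enz", "f1", "f2"):
            assert excluded not in got

    def test_neighbor_process_participants_included(self, fig1_map):
        """An EPN selection pulls its processes and their full
        substrate/product/effector sets."""
        got = expand_nodes(fig1_map, {"nbn1"})
        # p1 and p2 are nbn1's processes; their participants follow
        assert {"nbn1", "p1", "p2", "atm", "atm_p", "nbn2", "mrn"} <= got
        # mrn arrives as p2's product, so its members must come too
        assert {"nbn_m", "mre11", "rad50"} <= got
        # p4 touches mrn but mrn was not part of the non-process closure
        assert "p4" not in got

    def test_inflationary(self):
        for pd_map, rng in random_maps(20, master_seed=21):
            group = random_selection(pd_map, rng)
            assert group <= expand_nodes(pd_map, group)

    def test_monotone(self):
        for pd_map, rng in random_maps(20, master_seed=22):
            g2 = random_selection(pd_map, rng)
            g1 = NodeGroup(rng.sample(sorted(g2), rng.randint(1, len(g2))))
            assert expand_nodes(pd_map, g1) <= expand_nodes(pd_map, g2)

    def test_matches_naive_oracle(self):
        for pd_map, rng in random_maps(40, master_seed=23):
            for _ in range(4):
                group = random_selection(pd_map, rng, allow_empty=True)
                assert expand_nodes(pd_map, group) == NodeGroup(
                    naive_expand(pd_map, set(group)))

    def test_single_pass_not_idempotent(self, fig1_map):
        """Re-applying the closure may grow the set: entities added as a
        process's participants would pull in *their* other processes on a
        second pass.  The implementation must not iterate to fixpoint."""
        once = expand_nodes(fig1_map, {"nbn1"})
        twice = expand_nodes(fig1_map, once)
        assert once < twice  # strict growth on this map
        assert "p4" in twice and "chk_p" in twice


class TestShowSelected:
    def test_empty_selection_is_an_error(self, fig2_map):
        with pytest.raises(EmptySelectionError, match="at least one"):
            show_selected(fig2_map, NodeGroup())

    def test_full_selection_shows_everything(self, fig2_map):
        state = show_selected(fig2_map, fig2_map.all_nodes())
        assert state.shown_nodes == fig2_map.all_nodes()
        assert state.shown_arcs == frozenset(fig2_map.arcs)

    def test_arcs_shown_iff_both_endpoints_shown(self, fig1_map):
        state = show_selected(fig1_map, {"nbn1"})
        for arc_id, arc in fig1_map.arcs.items():
            both = arc.source_id in state.shown_nodes and arc.target_id in state.shown_nodes
            assert (arc_id in state.shown_arcs) == both

    def test_states_always_pass_all_five_invariants(self):
        for pd_map, rng in random_maps(40, master_seed=24):
            for _ in range(3):
                group = random_selection(pd_map, rng)
                report = check_invariants(pd_map, group, show_selected(pd_map, group))
                assert report.ok, f"seed map {pd_map.map_id}: {report}"


class TestHideSelected:
    def test_hide_nothing_keeps_everything(self, fig4_map):
        state = hide_selected(fig4_map, NodeGroup())
        assert state.shown_nodes == fig4_map.all_nodes()
        assert state.warning is None

    def test_hide_everything_shows_nothing_with_warning(self, fig4_map):
        state = hide_selected(fig4_map, fig4_map.all_nodes())
        assert state.empty
        assert state.warning is not None

    def test_hide_walkthrough_on_modification_chain(self, fig4_map):
        """Hiding the native state hides it, its process and that
        process's effector; the downstream chain and the shared
        compartment stay."""
        state = hide_selected(fig4_map, {"rsk"})
        assert state.shown_nodes == NodeGroup({"cytosol", "rsk_p", "rsk_pp", "p2"})
        hidden = fig4_map.all_nodes() - state.shown_nodes
        assert hidden == NodeGroup({"rsk", "p1", "erk"})

    def test_differs_from_naive_complement_expansion(self, fig4_map):
        """Expanding only the raw complement pulls the hidden node back:
        nothing would be hidden.  The two-stage closure must differ."""
        naive_shown = expand_nodes(fig4_map, fig4_map.all_nodes() - {"rsk"})
        assert naive_shown == fig4_map.all_nodes()
        assert hide_selected(fig4_map, {"rsk"}).shown_nodes < naive_shown

    def test_result_may_intersect_the_selections_closure(self, fig4_map):
        # the shared compartment lies in the closure of the hidden group
        # and is nevertheless kept visible by the complement's closure
        state = hide_selected(fig4_map, {"rsk"})
        assert "cytosol" in expand_nodes(fig4_map, {"rsk"})
        assert "cytosol" in state.shown_nodes

    def test_chained_hides_compose_over_visible_universe(self, fig1_map):
        first = hide_selected(fig1_map, {"atm"})
        assert "atm" not in first.shown_nodes
        second = hide_selected(fig1_map, {"chk_p"}, all_elems=first.shown_nodes)
        assert second.shown_nodes <= first.shown_nodes
        assert "chk_p" not in second.shown_nodes

    def test_expand_remaining_of_empty_is_everything(self, fig2_map):
        assert expand_remaining_nodes(fig2_map, NodeGroup()) == fig2_map.all_nodes()

    def test_expand_remaining_of_everything_is_empty(self, fig2_map):
        assert expand_remaining_nodes(fig2_map, fig2_map.all_nodes()) == NodeGroup()

    def test_hidden_states_pass_invariants_for_kept_seed(self):
        """The group the hide operation expanded (visible minus the
        selection's closure) plays the role of the initial selection."""
        for pd_map, rng in random_maps(30, master_seed=25):
            group = random_selection(pd_map, rng)
            state = hide_selected(pd_map, group)
            seed_group = pd_map.all_nodes() - expand_nodes(pd_map, group)
            report = check_invariants(pd_map, seed_group, state)
            assert report.ok, f"{pd_map.map_id}: {report}"


class TestCheckInvariants:
    def test_full_map_passes(self, fig1_map):
        state = VisibilityState(fig1_map.all_nodes(), frozenset(fig1_map.arcs))
        assert check_invariants(fig1_map, {"nbn1"}, state).ok

    def test_missing_complex_member_fails_invariant_5(self, fig1_map):
        shown = fig1_map.all_nodes() - {"mre11"}
        state = VisibilityState(shown, frozenset())
        report = check_invariants(fig1_map, {"nbn1"}, state)
        failed = dict((i, bad) for i, bad in report.failures())
        assert 5 in failed and "mre11" in failed[5]

    def test_hidden_parent_fails_invariant_4(self, fig2_map):
        shown = fig2_map.all_nodes() - {"muscle_cytosol"}
        state = VisibilityState(shown, frozenset())
        report = check_invariants(fig2_map, {"myosin"}, state)
        assert 4 in dict(report.failures())

    def test_hidden_selection_fails_invariant_1(self, minimal_map):
        state = VisibilityState(NodeGroup({"prc", "prd"}), frozenset())
        report = check_invariants(minimal_map, {"sub"}, state)
        assert 1 in dict(report.failures())

    def test_hidden_adjacent_process_fails_invariant_2(self, minimal_map):
        state = VisibilityState(NodeGroup({"sub"}), frozenset())
        report = check_invariants(minimal_map, {"sub"}, state)
        assert 2 in dict(report.failures())

    def test_hidden_participant_fails_invariant_3(self, minimal_map):
        state = VisibilityState(NodeGroup({"sub", "prc"}), frozenset())
        report = check_invariants(minimal_map, {"prc"}, state)
        failed = dict(report.failures())
        assert 3 in failed and "prd" in failed[3]

    def test_report_has_exactly_five_indexed_entries(self, minimal_map):
        state = VisibilityState(minimal_map.all_nodes(), frozenset(minimal_map.arcs))
        report = check_invariants(minimal_map, {"sub"}, state)
        assert [i for i, _, _ in report.results] == [1, 2, 3, 4, 5]


class TestInducedSubmap:
    def test_all_shown_copies_map(self, fig2_map):
        state = VisibilityState(fig2_map.all_nodes(), frozenset(fig2_map.arcs))
        assert_isomorphic(fig2_map, induced_submap(fig2_map, state))

    def test_none_shown_gives_empty_map(self, fig2_map):
        sub = induced_submap(fig2_map, VisibilityState(NodeGroup(), frozenset()))
        assert len(sub) == 0 and len(sub.arcs) == 0

    def test_non_ancestor_closed_state_rejected(self, fig2_map):
        state = VisibilityState(NodeGroup({"myosin"}), frozenset())
        with pytest.raises(ValidationError, match="ancestor"):
            induced_submap(fig2_map, state)

    def test_focus_pipeline_yields_valid_serializable_submaps(self):
        for pd_map, rng in random_maps(20, master_seed=26):
            group = random_selection(pd_map, rng)
            sub = induced_submap(pd_map, show_selected(pd_map, group))
            assert validate_structure(sub).ok
            assert_isomorphic(sub, parse_sbgnml(write_sbgnml(sub)))
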