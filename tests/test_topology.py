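"""Topology enumeration, canonicalization and motif classification."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import oscreen as oc
from oscreen.topology import (
    ACTIVATOR_INHIBITOR_MOTIFS,
    IsolationConvention,
    directed_cycles,
    repressilator_cycles,
    topology_from_dict,
    topology_to_dict,
    violates_convention,
)


def all_labeled(n):
    for signs in itertools.product((-1, 0, 1), repeat=n * n):
        yield oc.SignedTopology(n, signs)


sign_vectors_3 = st.lists(
    st.sampled_from([-1, 0, 1]), min_size=9, max_size=9
).map(tuple)


class TestCanonicalization:
    def test_repressilator_rotation_invariant(self, repressilator):
        rotated = repressilator.relabeled([1, 2, 0])
        assert oc.canonical_form(rotated) == oc.canonical_form(repressilator)

    def test_asymmetric_topology_is_own_canonical_form(self):
        t = oc.parse_topology("A B +1\nB C -1\nC A +1\nA A +1")
        # already lexicographically minimal over its orbit or not; the
        # canonical form must at least be idempotent and orbit-stable
        c = oc.canonical_form(t)
        assert oc.canonical_form(c) == c

    @settings(max_examples=200, deadline=None)
    @given(sign_vectors_3, st.permutations(range(3)))
    def test_relabeling_has_same_canonical_form(self, signs, perm):
        t = oc.SignedTopology(3, signs)
        assert oc.canonical_form(t.relabeled(perm)) == oc.canonical_form(t)

    def test_orbit_sizes_partition_labeled_universe(self):
        # every labeled 3-node configuration maps to exactly one orbit
        orbits = {}
        for t in all_labeled(3):
            orbits.setdefault(oc.canonical_form(t).signs, 0)
            orbits[oc.canonical_form(t).signs] += 1
        assert sum(orbits.values()) == 3**9
        for signs, size in orbits.items():
            assert 6 % size == 0 or size in (1, 2, 3, 6)
        orbits2 = {}
        for t in all_labeled(2):
            key = oc.canonical_form(t).signs
            orbits2[key] = orbits2.get(key, 0) + 1
        assert sum(orbits2.values()) == 3**4

    def test_topology_id_stable_under_relabeling(self, repressilator):
        assert oc.topology_id(repressilator.relabeled([2, 0, 1])) == oc.topology_id(
            repressilator
        )


class TestIsolation:
    def test_empty_topology_has_isolated_nodes(self):
        assert oc.has_isolated_node(oc.SignedTopology(3, (0,) * 9))

    def test_self_loop_does_not_rescue(self):
        t = oc.SignedTopology.from_links(
            3, [("A", "B", 1), ("B", "A", -1), ("C", "C", 1)]
        )
        assert oc.has_isolated_node(t)

    def test_isolated_count_matches_inclusion_exclusion(self):
        # 3 * 3^5 - 3 * 3^3 + 3^3 labeled 3-node configurations with at
        # least one node lacking any cross-link
        count = sum(1 for t in all_labeled(3) if oc.has_isolated_node(t))
        assert count == 3 * 3**5 - 3 * 3**3 + 3**3 == 675

    def test_universe_size_by_convention(self):
        sizes = {}
        for conv in IsolationConvention:
            sizes[conv] = len(oc.enumerate_topologies(conv))
        # the default convention reproduces the 1955-member universe
        assert sizes[IsolationConvention.IN_AND_OUT_CROSS] == 1955
        assert sizes[IsolationConvention.CROSS] == 3323

    def test_enumerated_topologies_are_canonical_and_unique(self):
        uni = oc.enumerate_topologies()
        assert len({t.signs for t in uni if t.n_nodes == 3}) == sum(
            1 for t in uni if t.n_nodes == 3
        )
        for t in uni[:50]:
            assert oc.canonical_form(t) == t
            assert not violates_convention(t, IsolationConvention.IN_AND_OUT_CROSS)


class TestMotifs:
    @pytest.mark.parametrize(
        "links, expected",
        [
            ("A B -1\nB C -1\nC A -1", {4}),  # bare repressilator
            ("A A +1\nA B +1\nB A -1", {3}),  # activator-inhibitor
            ("A B -1\nB C -1\nC A -1\nA A +1", {1}),  # no positive incoming
            ("A B -1\nB C -1\nC A -1\nA A +1\nB A +1", {2}),  # positive incoming
            ("A B +1\nB C +1\nC A -1", {5}),  # delayed negative feedback
            ("A B +1\nB A -1", {5}),  # two-node delayed negative feedback
            ("A A +1\nA C +1\nC B +1\nB A -1", {3}),  # relay variant (act arm)
            ("A A +1\nA B +1\nB C +1\nC A -1", {3}),  # relay variant (inh arm)
            ("A B +1\nB A +1", set()),  # mutual activation: no oscillator motif
        ],
    )
    def test_core_motif_examples(self, links, expected):
        assert set(oc.find_core_motifs(oc.parse_topology(links))) == expected

    def test_combined_category_label(self):
        # activator-inhibitor pair on (A, B) embedded alongside extra wiring
        t = oc.parse_topology("A A +1\nA B +1\nB A -1\nB C -1\nC A -1")
        motifs = oc.find_core_motifs(t)
        assert 3 in motifs
        label = oc.assign_category(t).label
        assert label.startswith("C") and "3" in label

    def test_category_labels(self, repressilator, activator_inhibitor):
        assert oc.assign_category(repressilator).label == "C4"
        assert oc.assign_category(activator_inhibitor).label == "C3"
        assert oc.assign_category(oc.parse_topology("A B +1\nB A +1")).label == (
            "uncategorized"
        )

    def test_category_is_relabeling_invariant(self, activator_inhibitor):
        rot = activator_inhibitor.relabeled([1, 0])
        assert (
            oc.assign_category(rot).label
            == oc.assign_category(activator_inhibitor).label
        )

    def test_motif_types_1_2_4_disjoint_per_cycle(self):
        # on a single repressilator subcycle the three repressilator
        # flavors cannot co-occur from the same autoregulated node
        for t_text, bad_pairs in [
            ("A B -1\nB C -1\nC A -1\nA A +1", {(2, 4)}),
        ]:
            motifs = oc.find_core_motifs(oc.parse_topology(t_text))
            assert not ({2, 4} <= motifs)

    def test_motif_library_is_configurable(self, activator_inhibitor):
        assert oc.find_core_motifs(
            activator_inhibitor, activator_inhibitor_motifs=()
        ) == frozenset()


class TestFeedback:
    def test_repressilator_has_negative_feedback(self, repressilator):
        assert oc.contains_negative_feedback(repressilator)

    def test_mutual_activation_has_none(self):
        assert not oc.contains_negative_feedback(oc.parse_topology("A B +1\nB A +1"))

    def test_negative_self_loop_counts(self):
        t = oc.SignedTopology.from_links(2, [("A", "A", -1), ("A", "B", 1), ("B", "A", 1)])
        assert oc.contains_negative_feedback(t)

    def test_repressilator_detection(self, repressilator, activator_inhibitor):
        assert oc.contains_repressilator(repressilator)
        assert not oc.contains_repressilator(activator_inhibitor)
        assert repressilator_cycles(repressilator) == [(0, 1, 2)]

    def test_directed_cycles_enumeration(self):
        t = oc.parse_topology("A A +1\nA B +1\nB A -1")
        assert set(directed_cycles(t)) == {(0,), (0, 1)}


class TestFormats:
    def test_text_round_trip(self, repressilator):
        text = str(repressilator)
        assert oc.parse_topology(text) == repressilator

    def test_json_round_trip(self, activator_inhibitor):
        d = topology_to_dict(activator_inhibitor)
        assert topology_from_dict(d) == activator_inhibitor

    def test_malformed_sign_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            oc.parse_topology("A B 2")
        with pytest.raises(ValueError, match="sign"):
            topology_from_dict({"n_nodes": 2, "links": [["A", "B", 2]]})

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError, match="node"):
            oc.parse_topology("A D +1")

    def test_save_load_round_trip(self, tmp_path, repressilator, activator_inhibitor):
        from oscreen.topology import load_topologies, save_topologies

        path = tmp_path / "topologies.json"
        save_topologies([repressilator, activator_inhibitor], path)
        loaded = load_topologies(path)
        assert [oc.canonical_form(t) for t in loaded] == [
            oc.canonical_form(repressilator),
            oc.canonical_form(activator_inhibitor),
        ]
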