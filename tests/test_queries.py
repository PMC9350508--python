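"""Connectivity query suite: worked examples, oracles, and invariants."""

import numpy as np
import pandas as pd
import pytest

import neugraph as ng
from neugraph.synthetic import TOY_SITES

from conftest import graph_world, random_graph_world, small_world

nx = pytest.importorskip("networkx")


class TestPartners:
    def test_toy_min_weight(self, toy_store):
        rows = ng.partners(toy_store, 100, "outgoing", min_weight=2, scope="segments")
        assert [(r.partner_body, r.weight) for r in rows] == [(200, 3)]

    def test_toy_all_segments(self, toy_store):
        rows = ng.partners(toy_store, 100, "outgoing", scope="segments")
        assert [(r.partner_body, r.weight) for r in rows] == [(200, 3), (300, 1)]

    def test_confidence_filter_recomputes_from_links(self, toy_store):
        rows = ng.partners(toy_store, 100, "outgoing", min_confidence=0.8)
        assert [(r.partner_body, r.weight) for r in rows] == [(200, 1)]

    def test_unknown_body(self, toy_store):
        with pytest.raises(ng.NotFoundError):
            ng.partners(toy_store, 999, "outgoing")

    @pytest.mark.parametrize("seed", range(5))
    def test_aggregate_equals_link_traversal(self, seed):
        """Partner weights from stored connections equal recomputation from links."""
        _, _, store = small_world(seed)
        for body in list(store.segments)[:20]:
            for direction in ("outgoing", "incoming"):
                fast = {
                    r.partner_body: r.weight
                    for r in ng.partners(store, body, direction, scope="segments")
                }
                slow: dict[int, int] = {}
                for link in store.links_of_body(body, direction):
                    other = link.post_site if direction == "outgoing" else link.pre_site
                    partner = store.sites[other].body_id
                    slow[partner] = slow.get(partner, 0) + 1
                assert fast == slow

    def test_flow_conservation(self):
        """Summed outgoing partner weights equal the body's pre-side link count."""
        _, _, store = small_world(7)
        for body in store.segments:
            out = sum(r.weight for r in ng.partners(store, body, "outgoing",
                                                    scope="segments"))
            assert out == len(store.links_of_body(body, "outgoing"))


class TestTracedWeight:
    def test_toy_outgoing(self, toy_store):
        assert ng.traced_partner_weight(toy_store, 100, "outgoing") == 3

    def test_no_outputs(self, toy_store):
        assert ng.traced_partner_weight(toy_store, 300, "outgoing") == 0

    def test_matches_scan(self):
        _, _, store = small_world(2)
        for body in store.neuron_ids()[:10]:
            want = sum(
                c.weight for (a, b), c in store.connections.items()
                if a == body and (store.segments[b].status or "").lower() == "traced"
            )
            assert ng.traced_partner_weight(store, body, "outgoing") == want


class TestPaths:
    def test_toy_direct(self, toy_store):
        got = ng.paths(toy_store, 100, 300, max_len=2, scope="segments")
        assert [p.bodies for p in got] == [(100, 300)]

    def test_no_autapse_means_no_self_path(self, toy_store):
        assert ng.paths(toy_store, 100, 100, max_len=3) == []

    def test_autapse_is_the_only_self_path(self):
        store = graph_world(2, {(1, 1): 2, (1, 2): 1, (2, 1): 1})
        got = ng.paths(store, 1, 1, max_len=3)
        assert [(p.bodies, p.weights) for p in got] == [((1, 1), (2,))]

    def test_budget_exceeded_raises(self):
        store = graph_world(6, {(a, b): 5 for a in range(1, 7) for b in range(1, 7) if a != b})
        with pytest.raises(ng.SearchBudgetExceeded):
            ng.paths(store, 1, 6, max_len=5, expansion_cap=3)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        """paths() equals a networkx all-simple-paths oracle on small digraphs."""
        rng = np.random.default_rng(seed)
        store, edges, n = random_graph_world(rng)
        min_weight = int(rng.integers(1, 4))
        max_len = int(rng.integers(1, 5))
        g = nx.DiGraph((a, b) for (a, b), w in edges.items() if w >= min_weight)
        g.add_nodes_from(range(1, n + 1))
        src, dst = int(rng.integers(1, n + 1)), int(rng.integers(1, n + 1))
        if src == dst:
            return
        got = [p.bodies for p in ng.paths(store, src, dst, max_len, min_weight)]
        want = sorted(
            (tuple(p) for p in nx.all_simple_paths(g, src, dst, cutoff=max_len)),
            key=lambda p: (len(p), p),
        )
        assert got == want


class TestShortestPaths:
    def test_toy_direct(self, toy_store):
        got = ng.shortest_paths(toy_store, 100, 300, scope="segments")
        assert [p.bodies for p in got] == [(100, 300)]

    def test_dead_end(self, toy_store):
        assert ng.shortest_paths(toy_store, 300, 200, scope="segments") == []

    @pytest.mark.parametrize("seed", range(30))
    def test_length_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed + 1000)
        store, edges, n = random_graph_world(rng)
        g = nx.DiGraph(edges.keys())
        g.add_nodes_from(range(1, n + 1))
        src, dst = int(rng.integers(1, n + 1)), int(rng.integers(1, n + 1))
        if src == dst:
            return
        got = ng.shortest_paths(store, src, dst)
        try:
            d = nx.shortest_path_length(g, src, dst)
        except nx.NetworkXNoPath:
            assert got == []
            return
        assert got and all(len(p) == d for p in got)
        want = sorted(tuple(p) for p in nx.all_shortest_paths(g, src, dst))
        assert [p.bodies for p in got] == want


class TestReciprocal:
    def test_toy_pair(self, toy_store):
        assert ng.is_reciprocal(toy_store, 100, 200)
        assert not ng.is_reciprocal(toy_store, 100, 300)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        store, edges, n = random_graph_world(rng)
        for a in range(1, n + 1):
            for b in range(1, n + 1):
                assert ng.is_reciprocal(store, a, b) == ng.is_reciprocal(store, b, a)


class TestRoiProjection:
    def test_toy_alpha_to_beta(self, toy_store):
        assert ng.roi_projection_neurons(toy_store, "alpha", "beta") == [200]

    def test_toy_beta_to_alpha(self, toy_store):
        assert ng.roi_projection_neurons(toy_store, "beta", "alpha") == [100]

    def test_unknown_roi(self, toy_store):
        with pytest.raises(ng.InputError):
            ng.roi_projection_neurons(toy_store, "gamma", "beta")


class TestCommonPartners:
    def test_toy_shared_input(self, toy_store):
        rows = ng.common_partners(toy_store, {200, 300}, "incoming", scope="segments")
        assert [(r.partner_body, r.weights) for r in rows] == [(100, {200: 3, 300: 1})]

    def test_toy_disjoint_outputs(self, toy_store):
        assert ng.common_partners(toy_store, {100, 200}, "outgoing",
                                  scope="segments") == []

    def test_singleton_equals_partners(self):
        _, _, store = small_world(4)
        body = store.neuron_ids()[0]
        single = ng.common_partners(store, {body}, "outgoing")
        plain = ng.partners(store, body, "outgoing")
        assert {r.partner_body: r.weights[body] for r in single} == {
            r.partner_body: r.weight for r in plain
        }


def _two_profile_store(profile_a, profile_b):
    """Two neurons with given (pre-in-a, pre-in-b) leaf profiles, no links."""
    rois = [
        ng.RoiNode("brain"),
        ng.RoiNode("a", "brain", ((0, 0, 0), (10, 10, 10))),
        ng.RoiNode("b", "brain", ((10, 0, 0), (20, 10, 10))),
    ]
    bodies, sites = [], []
    sid = 0
    for body, (na, nb) in ((1, profile_a), (2, profile_b)):
        bodies.append({"body_id": body, "instance": "", "type": "T",
                       "status": "Traced", "size": 10**8})
        for _ in range(na):
            sid += 1
            sites.append({"site_id": sid, "body_id": body, "kind": "pre",
                          "x": 1, "y": 1, "z": 1, "confidence": 0.9})
        for _ in range(nb):
            sid += 1
            sites.append({"site_id": sid, "body_id": body, "kind": "pre",
                          "x": 11, "y": 1, "z": 1, "confidence": 0.9})
    bundle = ng.RawBundle(
        bodies=pd.DataFrame(bodies),
        sites=pd.DataFrame(sites),
        links=pd.DataFrame(columns=["pre_site_id", "post_site_id"]),
        rois=rois,
    )
    store = ng.build_aggregates(bundle)
    store.promote()
    return store


class TestSimilarity:
    def test_proportional_profiles_score_one(self):
        store = _two_profile_store((2, 4), (1, 2))
        [(body, sim)] = ng.similar_by_roi_profile(store, 1, top_k=1)
        assert body == 2 and sim == pytest.approx(1.0)

    def test_disjoint_supports_score_zero(self):
        store = _two_profile_store((3, 0), (0, 5))
        [(body, sim)] = ng.similar_by_roi_profile(store, 1, top_k=1)
        assert body == 2 and sim == pytest.approx(0.0)

    def test_zero_synapse_body_is_undefined(self, toy_store):
        store = _two_profile_store((1, 0), (0, 0))
        with pytest.raises(ng.UndefinedMetricError):
            ng.similar_by_roi_profile(store, 2, top_k=1)


class TestCellTypeSummary:
    def test_identical_connectivity_members(self):
        # bodies 1 and 2 (same type via set_property) both project onto 3
        store = graph_world(3, {(1, 3): 4, (2, 3): 4})
        ng.edits.apply_set_property(store, 1, "type", "X")
        ng.edits.apply_set_property(store, 2, "type", "X")
        ng.edits.apply_set_property(store, 3, "type", "Y")
        members, sim = ng.cell_type_summary(store, "X")
        assert members == [1, 2]
        assert sim[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(sim), 1.0)

    def test_disjoint_partner_types(self):
        store = graph_world(4, {(1, 3): 2, (2, 4): 2})
        ng.edits.apply_set_property(store, 1, "type", "X")
        ng.edits.apply_set_property(store, 2, "type", "X")
        ng.edits.apply_set_property(store, 3, "type", "A")
        ng.edits.apply_set_property(store, 4, "type", "B")
        _, sim = ng.cell_type_summary(store, "X")
        assert sim[0, 1] == pytest.approx(0.0)

    def test_toy_single_member(self, toy_store):
        members, sim = ng.cell_type_summary(toy_store, "KCa")
        assert members == [100]
        assert sim.shape == (1, 1) and sim[0, 0] == 1.0

    def test_unknown_type(self, toy_store):
        with pytest.raises(ng.NotFoundError):
            ng.cell_type_summary(toy_store, "ZZZ")


class TestRoiMatrix:
    def test_toy_count_mode(self, toy_store):
        # both neurons project beta->beta: 100 via q1/p3, 200 via r2,r3/t1
        assert ng.roi_connectivity_matrix(toy_store, "count") == {
            ("alpha", "beta"): 1.0, ("beta", "alpha"): 1.0, ("beta", "beta"): 2.0,
        }

    def test_toy_weighted_alpha_beta_share(self, toy_store):
        matrix = ng.roi_connectivity_matrix(toy_store, "weighted")
        assert matrix[("alpha", "beta")] == pytest.approx(1 / 3)

    def test_single_roi_support(self):
        store = graph_world(2, {(1, 2): 3})  # all sites inside leaf "brain"
        matrix = ng.roi_connectivity_matrix(store, "count")
        assert set(matrix) <= {("brain", "brain")}


class TestCountTypes:
    @pytest.mark.parametrize("pattern,expected", [("KC.*", 1), (".*", 2), ("ZZZ", 0)])
    def test_toy_patterns(self, toy_store, pattern, expected):
        assert ng.count_types_matching(toy_store, pattern) == expected

    def test_invalid_pattern(self, toy_store):
        with pytest.raises(ng.InputError):
            ng.count_types_matching(toy_store, "(")
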