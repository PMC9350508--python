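"""Incremental merge/split/property edits versus full rebuild."""

import numpy as np
import pytest

import neugraph as ng
from neugraph.edits import EditEvent, LogApplicationError, apply_log, read_log, write_log
from neugraph.synthetic import TOY_SITES, toy

from conftest import edit_bundle_raw, small_world


class TestMerge:
    def test_toy_merge_redirects_weight(self, fresh_toy_store):
        ng.apply_merge(fresh_toy_store, 200, 300)
        assert fresh_toy_store.get_connection(100, 200).weight == 4
        assert (100, 300) not in fresh_toy_store.connections
        assert 300 not in fresh_toy_store.segments
        assert fresh_toy_store.get_body(200).size == 30_010_000

    def test_toy_merge_creates_autapse(self, fresh_toy_store):
        # every link among the merged pair (p1-p3 onto 200's posts, t1 onto q1)
        # becomes an autapse contribution
        ng.apply_merge(fresh_toy_store, 100, 200)
        assert fresh_toy_store.get_connection(100, 100).weight == 4

    def test_merge_empty_source_only_removes_it(self, fresh_toy_store):
        bundle = toy()
        bundle.bodies.loc[len(bundle.bodies)] = {
            "body_id": 400, "instance": "", "type": "", "status": "", "size": 5,
        }
        store = ng.build_aggregates(bundle)
        store.promote()
        before = {p: c.weight for p, c in store.connections.items()}
        ng.apply_merge(store, 100, 400)
        assert 400 not in store.segments
        assert {p: c.weight for p, c in store.connections.items()} == before

    def test_merge_into_self_rejected(self, fresh_toy_store):
        with pytest.raises(ng.InputError):
            ng.apply_merge(fresh_toy_store, 100, 100)

    def test_merge_unknown_body(self, fresh_toy_store):
        with pytest.raises(ng.NotFoundError):
            ng.apply_merge(fresh_toy_store, 100, 999)


class TestSplit:
    def test_split_inverts_merge_on_toy(self, fresh_toy_store):
        original = ng.build_aggregates(toy())
        original.promote()
        ng.apply_merge(fresh_toy_store, 200, 300)
        ng.apply_split(fresh_toy_store, 200, 300, [TOY_SITES["s1"]], moved_size=10_000)
        fresh_toy_store.promote()
        assert fresh_toy_store.equals(original, ignore_neuron_flags=True)

    def test_split_moving_nothing(self, fresh_toy_store):
        before = {p: c.weight for p, c in fresh_toy_store.connections.items()}
        ng.apply_split(fresh_toy_store, 100, 900, [])
        assert fresh_toy_store.get_body(900).pre_count == 0
        assert {p: c.weight for p, c in fresh_toy_store.connections.items()} == before

    def test_split_collision_and_foreign_site(self, fresh_toy_store):
        with pytest.raises(ng.InputError):
            ng.apply_split(fresh_toy_store, 100, 200, [])  # 200 exists
        with pytest.raises(ng.InputError):
            ng.apply_split(fresh_toy_store, 100, 900, [TOY_SITES["r1"]])  # owned by 200

    @pytest.mark.parametrize("seed", range(5))
    def test_split_then_merge_back_is_identity(self, seed):
        _, _, store = small_world(seed)
        rng = np.random.default_rng(seed)
        body = store.neuron_ids()[int(rng.integers(len(store.neuron_ids())))]
        sites = [s.site_id for s in store.body_sites(body)][:3]
        before_weights = {p: c.weight for p, c in store.connections.items()}
        before_info = {b: dict(r.roi_info) for b, r in store.segments.items()}
        ng.apply_split(store, body, 999_999, sites, moved_size=100)
        ng.apply_merge(store, body, 999_999)
        assert {p: c.weight for p, c in store.connections.items()} == before_weights
        assert {b: dict(r.roi_info) for b, r in store.segments.items()} == before_info


class TestConservation:
    def test_totals_invariant_under_edits(self, fresh_toy_store):
        n_sites, n_links = len(fresh_toy_store.sites), len(fresh_toy_store.links)
        ng.apply_merge(fresh_toy_store, 200, 300)
        ng.apply_split(fresh_toy_store, 100, 901, [TOY_SITES["p1"]])
        assert len(fresh_toy_store.sites) == n_sites
        assert len(fresh_toy_store.links) == n_links
        total = sum(c.weight for c in fresh_toy_store.connections.values())
        assert total == n_links


class TestApplyLog:
    def test_empty_log_is_noop(self, fresh_toy_store):
        reference = ng.build_aggregates(toy())
        reference.promote()
        apply_log(fresh_toy_store, [])
        assert fresh_toy_store.equals(reference)

    def test_single_event_fold_equals_direct_apply(self, fresh_toy_store):
        direct = ng.build_aggregates(toy())
        direct.promote()
        ng.apply_merge(direct, 200, 300)
        direct.promote()
        apply_log(fresh_toy_store, [
            EditEvent(sequence_number=1, action="merge", target=200, source=300)
        ])
        assert fresh_toy_store.equals(direct)

    def test_out_of_order_rejected(self, fresh_toy_store):
        events = [
            EditEvent(sequence_number=2, action="merge", target=200, source=300),
            EditEvent(sequence_number=1, action="set_property", body=100,
                      key="status", value="Orphan"),
        ]
        with pytest.raises(ng.InputError, match="strictly increasing"):
            apply_log(fresh_toy_store, events)

    def test_replay_is_warned_noop(self, fresh_toy_store):
        events = [EditEvent(sequence_number=1, action="set_property", body=100,
                            key="type", value="KCb")]
        apply_log(fresh_toy_store, events)
        with pytest.warns(UserWarning, match="already applied"):
            apply_log(fresh_toy_store, events)
        assert fresh_toy_store.get_body(100).type == "KCb"

    def test_mid_log_failure_reports_last_applied(self, fresh_toy_store):
        events = [
            EditEvent(sequence_number=1, action="set_property", body=100,
                      key="type", value="KCb"),
            EditEvent(sequence_number=2, action="merge", target=200, source=999),
        ]
        with pytest.raises(LogApplicationError, match="sequence 1"):
            apply_log(fresh_toy_store, events)
        assert fresh_toy_store.get_body(100).type == "KCb"  # first event held

    def test_log_file_round_trip(self, tmp_path):
        events = [
            EditEvent(sequence_number=1, action="merge", target=200, source=300),
            EditEvent(sequence_number=2, action="split", body=200, new_body=300,
                      moved_site_ids=(TOY_SITES["s1"],), moved_size=10_000),
            EditEvent(sequence_number=3, action="set_property", body=100,
                      key="status", value="Orphan"),
        ]
        path = tmp_path / "edits.jsonl"
        write_log(events, path)
        assert read_log(path) == events


def random_log(store: ng.GraphStore, rng: np.random.Generator, n_events: int = 6):
    """A random valid edit log against (a copy of the state of) *store*."""
    alive = sorted(store.segments)
    owned = {b: [s.site_id for s in store.body_sites(b)] for b in alive}
    next_body = 10_000_000
    events = []
    for seq in range(1, n_events + 1):
        action = rng.choice(["merge", "split", "set_property"], p=[0.4, 0.4, 0.2])
        if action == "merge" and len(alive) >= 2:
            target, source = (int(x) for x in rng.choice(alive, size=2, replace=False))
            events.append(EditEvent(sequence_number=seq, action="merge",
                                    target=target, source=source))
            owned[target] = owned[target] + owned[source]
            del owned[source]
            alive.remove(source)
        elif action == "split":
            body = int(rng.choice(alive))
            pool = owned[body]
            k = int(rng.integers(0, len(pool) + 1)) if pool else 0
            moved = [int(s) for s in rng.choice(pool, size=k, replace=False)] if k else []
            next_body += 1
            events.append(EditEvent(sequence_number=seq, action="split", body=body,
                                    new_body=next_body, moved_site_ids=tuple(moved),
                                    moved_size=int(rng.integers(0, 1000))))
            owned[next_body] = moved
            owned[body] = [s for s in pool if s not in set(moved)]
            alive.append(next_body)
            alive.sort()
        else:
            body = int(rng.choice(alive))
            key = str(rng.choice(["instance", "type", "status"]))
            events.append(EditEvent(sequence_number=seq, action="set_property",
                                    body=body, key=key,
                                    value=str(rng.choice(["Traced", "Orphan", "KCx"]))))
    return events


class TestIncrementalEqualsRebuild:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_logs_match_raw_rebuild(self, seed):
        """Folding a log incrementally equals rebuilding from edited raw tables."""
        bundle, _, store = small_world(seed)
        rng = np.random.default_rng(seed + 77)
        events = random_log(store, rng)
        apply_log(store, events)
        rebuilt = ng.build_aggregates(edit_bundle_raw(bundle, events))
        rebuilt.promote()
        assert store.equals(rebuilt)
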