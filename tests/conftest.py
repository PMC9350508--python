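"""Shared fixtures and independent brute-force oracles.

The oracles here recompute store aggregates directly from the raw tables
(pandas joins, explicit parent-map walks) without going through the
store's own aggregate builder, so agreement between the two routes is a
genuine cross-check.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
import pytest

import neugraph as ng
from neugraph.synthetic import TOY_SITES, WorldConfig, generate, toy


@pytest.fixture(scope="session")
def toy_store() -> ng.GraphStore:
    store = ng.build_aggregates(toy())
    store.promote()
    return store


@pytest.fixture()
def fresh_toy_store() -> ng.GraphStore:
    """A private TOY store for tests that mutate it."""
    store = ng.build_aggregates(toy())
    store.promote()
    return store


S = TOY_SITES


def small_world(seed: int, **overrides):
    """A small synthetic world: (bundle, truth, promoted store)."""
    params = dict(n_neurons=12, n_fragments=30, synapses_per_neuron=8.0,
                  roi_grid=(2, 2), roi_cell=256, seed=seed)
    params.update(overrides)
    bundle, truth = generate(WorldConfig(**params))
    store = ng.build_aggregates(bundle)
    store.promote()
    return bundle, truth, store


def graph_world(n_bodies: int, edge_weights: dict[tuple[int, int], int]) -> ng.GraphStore:
    """Build a store whose connection graph is exactly *edge_weights*.

    Bodies are 1..n, all promoted (status set); each unit of weight on an
    edge becomes one pre site with a single link to a fresh post site.
    """
    bodies = pd.DataFrame(
        [{"body_id": b, "instance": "", "type": "", "status": "Traced", "size": 10**8}
         for b in range(1, n_bodies + 1)]
    )
    site_rows, link_rows = [], []
    sid = 0
    for (a, b), w in sorted(edge_weights.items()):
        for _ in range(w):
            sid += 1
            pre = sid
            site_rows.append({"site_id": pre, "body_id": a, "kind": "pre",
                              "x": 1, "y": 1, "z": 1, "confidence": 0.9})
            sid += 1
            site_rows.append({"site_id": sid, "body_id": b, "kind": "post",
                              "x": 1, "y": 1, "z": 1, "confidence": 0.9})
            link_rows.append({"pre_site_id": pre, "post_site_id": sid})
    sites = pd.DataFrame(site_rows, columns=["site_id", "body_id", "kind",
                                             "x", "y", "z", "confidence"])
    links = pd.DataFrame(link_rows, columns=["pre_site_id", "post_site_id"])
    bundle = ng.RawBundle(bodies=bodies, sites=sites, links=links,
                          rois=[ng.RoiNode("brain", None, ((0, 0, 0), (4, 4, 4)))])
    store = ng.build_aggregates(bundle)
    store.promote()
    return store


def random_graph_world(rng: np.random.Generator, max_bodies: int = 12,
                       max_edges: int = 30):
    """Random small digraph world plus its edge-weight map."""
    n = int(rng.integers(2, max_bodies + 1))
    n_edges = int(rng.integers(1, max_edges + 1))
    edges: dict[tuple[int, int], int] = {}
    for _ in range(n_edges):
        a = int(rng.integers(1, n + 1))
        b = int(rng.integers(1, n + 1))
        edges[(a, b)] = edges.get((a, b), 0) + int(rng.integers(1, 4))
    return graph_world(n, edges), edges, n


# ----------------------------------------------------------------------
# brute-force oracles over raw tables
# ----------------------------------------------------------------------

def parent_map(bundle: ng.RawBundle) -> dict[str, str | None]:
    return {r.name: r.parent for r in bundle.rois}


def ancestors_closure(roi: str, parents: dict[str, str | None]) -> set[str]:
    out = set()
    cur: str | None = roi
    while cur is not None:
        out.add(cur)
        cur = parents[cur]
    return out


def leaf_boxes(bundle: ng.RawBundle) -> dict[str, tuple]:
    names = {r.name for r in bundle.rois}
    with_children = {r.parent for r in bundle.rois if r.parent}
    return {r.name: r.box for r in bundle.rois
            if r.name in names - with_children and r.box is not None}


def brute_site_rois(bundle: ng.RawBundle) -> dict[int, set[str]]:
    """Site → full ROI membership, by direct box tests and parent walking."""
    parents = parent_map(bundle)
    boxes = leaf_boxes(bundle)
    out: dict[int, set[str]] = {}
    for row in bundle.sites.itertuples(index=False):
        hit: set[str] = set()
        x, y, z = int(row.x), int(row.y), int(row.z)
        for leaf, ((x0, y0, z0), (x1, y1, z1)) in boxes.items():
            if x0 <= x < x1 and y0 <= y < y1 and z0 <= z < z1:
                hit |= ancestors_closure(leaf, parents)
        out[int(row.site_id)] = hit
    return out


def brute_weights(bundle: ng.RawBundle) -> dict[tuple[int, int], int]:
    owner = bundle.sites.set_index("site_id")["body_id"]
    w: Counter = Counter()
    for row in bundle.links.itertuples(index=False):
        w[(int(owner[row.pre_site_id]), int(owner[row.post_site_id]))] += 1
    return dict(w)


def brute_segment_roi_info(bundle: ng.RawBundle) -> dict[int, dict]:
    memberships = brute_site_rois(bundle)
    info: dict[int, dict] = {int(b): {} for b in bundle.bodies["body_id"].astype(int)}
    for row in bundle.sites.itertuples(index=False):
        body = int(row.body_id)
        for roi in memberships[int(row.site_id)]:
            entry = info[body].setdefault(roi, {})
            entry[row.kind] = entry.get(row.kind, 0) + 1
    return {b: v for b, v in info.items()}


def brute_connection_roi_info(bundle: ng.RawBundle) -> dict[tuple[int, int], dict]:
    memberships = brute_site_rois(bundle)
    owner = {int(r.site_id): int(r.body_id)
             for r in bundle.sites.itertuples(index=False)}
    per_pair_posts: dict[tuple[int, int], list[int]] = {}
    per_pair_pres: dict[tuple[int, int], set[int]] = {}
    for row in bundle.links.itertuples(index=False):
        p, q = int(row.pre_site_id), int(row.post_site_id)
        pair = (owner[p], owner[q])
        per_pair_posts.setdefault(pair, []).append(q)
        per_pair_pres.setdefault(pair, set()).add(p)
    out: dict[tuple[int, int], dict] = {}
    for pair in per_pair_posts:
        info: dict = {}
        for q in per_pair_posts[pair]:
            for roi in memberships[q]:
                entry = info.setdefault(roi, {})
                entry["post"] = entry.get("post", 0) + 1
        for p in per_pair_pres[pair]:
            for roi in memberships[p]:
                entry = info.setdefault(roi, {})
                entry["pre"] = entry.get("pre", 0) + 1
        out[pair] = info
    return out


def edit_bundle_raw(bundle: ng.RawBundle, events) -> ng.RawBundle:
    """Apply edit events naively to the raw tables (rebuild-path oracle)."""
    bodies = bundle.bodies.copy()
    bodies["body_id"] = bodies["body_id"].astype(int)
    bodies["size"] = bodies["size"].astype(int)
    sites = bundle.sites.copy()
    sites["site_id"] = sites["site_id"].astype(int)
    sites["body_id"] = sites["body_id"].astype(int)
    bodies = bodies.set_index("body_id", drop=False)
    for ev in events:
        if ev.action == "merge":
            sites.loc[sites["body_id"] == ev.source, "body_id"] = ev.target
            bodies.loc[ev.target, "size"] += bodies.loc[ev.source, "size"]
            bodies = bodies.drop(index=ev.source)
        elif ev.action == "split":
            moved = set(ev.moved_site_ids)
            sites.loc[sites["site_id"].isin(moved), "body_id"] = ev.new_body
            bodies.loc[ev.body, "size"] -= ev.moved_size
            bodies.loc[ev.new_body] = {
                "body_id": ev.new_body, "instance": "", "type": "",
                "status": "", "size": ev.moved_size,
            }
        else:
            bodies.loc[ev.body, ev.key] = ev.value or ""
    return ng.RawBundle(
        bodies=bodies.reset_index(drop=True), sites=sites, links=bundle.links.copy(),
        rois=list(bundle.rois), site_rois=bundle.site_rois, dataset=bundle.dataset,
    )
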