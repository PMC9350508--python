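"""Canonical connectivity queries over a consistent :class:`GraphStore`.

These are the operations an interactive connectome browser exposes:
partner tables ordered by connection strength, bounded path search,
reciprocity tests, region-to-region projection counts, common partners of
a neuron set, ROI-profile similarity, and cell-type summaries.

Neuron scope is the default everywhere — users rarely want a long list of
tiny unnamed fragments — with segment scope as an explicit opt-in.  All
outputs are deterministically ordered.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, NotFoundError, SearchBudgetExceeded, UndefinedMetricError
from .model import Direction, GraphStore, _compile

DEFAULT_EXPANSION_CAP = 100_000


@dataclass(frozen=True)
class PartnerRow:
    """One partner of a queried body, with the connection weight."""

    partner_body: int
    weight: int
    partner_type: str | None = None
    partner_instance: str | None = None
    partner_status: str | None = None
    direction: Direction = "outgoing"


@dataclass(frozen=True)
class CommonPartnerRow:
    """A partner shared by every body in a queried set; per-body weights."""

    partner_body: int
    weights: dict[int, int] = field(hash=False, default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.weights.values())


@dataclass(frozen=True)
class Path:
    """A directed path; ``weights[i]`` is the strength of hop i."""

    bodies: tuple[int, ...]
    weights: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.weights)


def _partner_ids(store: GraphStore, body: int, direction: Direction) -> list[int]:
    if direction == "outgoing":
        return sorted(store._out.get(body, ()))
    if direction == "incoming":
        return sorted(store._in.get(body, ()))
    raise InputError(f"unknown direction {direction!r}")


def _pair_weight(
    store: GraphStore, pre: int, post: int, min_confidence: float
) -> int:
    """Connection weight, recomputed from links when a confidence floor applies."""
    if min_confidence <= 0:
        conn = store.connections.get((pre, post))
        return conn.weight if conn else 0
    n = 0
    for link in store.pair_links(pre, post):
        if (
            store.sites[link.pre_site].confidence >= min_confidence
            and store.sites[link.post_site].confidence >= min_confidence
        ):
            n += 1
    return n


def partners(
    store: GraphStore,
    body: int,
    direction: Direction,
    min_weight: int = 1,
    scope: str = "neurons",
    min_confidence: float = 0.0,
) -> list[PartnerRow]:
    """Inputs or outputs of *body* ordered by connection strength.

    With ``min_confidence > 0`` the effective weight counts only links
    whose pre **and** post site confidences reach the threshold; this is
    recomputed from the individual links, not the stored aggregate.
    """
    store.get_body(body)
    rows = []
    for partner in _partner_ids(store, body, direction):
        if not store.in_scope(partner, scope):
            continue
        pre, post = (body, partner) if direction == "outgoing" else (partner, body)
        w = _pair_weight(store, pre, post, min_confidence)
        if w >= min_weight:
            rec = store.segments[partner]
            rows.append(
                PartnerRow(partner, w, rec.type, rec.instance, rec.status, direction)
            )
    rows.sort(key=lambda r: (-r.weight, r.partner_body))
    return rows


def traced_partner_weight(store: GraphStore, body: int, direction: Direction) -> int:
    """Total connection weight from *body* to partners with status "traced"."""
    store.get_body(body)
    total = 0
    for partner in _partner_ids(store, body, direction):
        if (store.segments[partner].status or "").lower() != "traced":
            continue
        pre, post = (body, partner) if direction == "outgoing" else (partner, body)
        total += store.connections[(pre, post)].weight
    return total


class _Budget:
    __slots__ = ("used", "cap")

    def __init__(self, cap: int):
        self.used = 0
        self.cap = cap

    def spend(self) -> None:
        self.used += 1
        if self.used > self.cap:
            raise SearchBudgetExceeded(self.used, self.cap)


def _adjacency(store: GraphStore, min_weight: int) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for (pre, post), conn in store.connections.items():
        if conn.weight >= min_weight:
            adj.setdefault(pre, []).append(post)
    for nbrs in adj.values():
        nbrs.sort()
    return adj


def paths(
    store: GraphStore,
    source: int,
    target: int,
    max_len: int,
    min_weight: int = 1,
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
    scope: str = "neurons",
) -> list[Path]:
    """All simple directed paths source→target of at most *max_len* hops.

    Every hop must have connection weight ≥ *min_weight*; intermediate
    bodies must lie in *scope* (the endpoints themselves are exempt, since
    the caller named them explicitly).  Results are sorted by length, then
    lexicographically by body sequence.  If the search expands more than
    *expansion_cap* nodes a :class:`SearchBudgetExceeded` is raised rather
    than returning a silent partial answer.
    """
    store.get_body(source)
    store.get_body(target)
    if max_len < 1:
        raise InputError("max_len must be >= 1")
    if source == target:
        # only a direct autapse counts; cycles through other bodies revisit
        # the source and are not simple paths
        conn = store.connections.get((source, source))
        if conn is not None and conn.weight >= min_weight:
            return [Path((source, source), (conn.weight,))]
        return []
    adj = _adjacency(store, min_weight)
    budget = _Budget(expansion_cap)
    found: list[Path] = []
    stack: list[int] = [source]
    weights: list[int] = []

    def dfs(node: int) -> None:
        budget.spend()
        if len(weights) >= max_len:
            return
        for nxt in adj.get(node, ()):
            if nxt == target:
                found.append(Path(tuple(stack) + (target,),
                                  tuple(weights) + (store.connections[(node, nxt)].weight,)))
                continue
            if nxt in on_path or not store.in_scope(nxt, scope):
                continue
            on_path.add(nxt)
            stack.append(nxt)
            weights.append(store.connections[(node, nxt)].weight)
            dfs(nxt)
            weights.pop()
            stack.pop()
            on_path.discard(nxt)

    on_path = {source}
    dfs(source)
    found.sort(key=lambda p: (len(p), p.bodies))
    return found


def shortest_paths(
    store: GraphStore,
    source: int,
    target: int,
    min_weight: int = 1,
    expansion_cap: int = DEFAULT_EXPANSION_CAP,
    scope: str = "neurons",
) -> list[Path]:
    """All minimum-hop directed paths source→target.

    A deterministic node-expansion budget replaces a wall-clock timeout so
    results are reproducible.  Returns ``[]`` when no path exists.
    """
    store.get_body(source)
    store.get_body(target)
    if source == target:
        return paths(store, source, target, 1, min_weight, expansion_cap, scope)
    adj = _adjacency(store, min_weight)
    # breadth-first distance from source, respecting scope on intermediates
    dist = {source: 0}
    budget = _Budget(expansion_cap)
    queue = deque([source])
    while queue:
        node = queue.popleft()
        budget.spend()
        for nxt in adj.get(node, ()):
            if nxt in dist:
                continue
            if nxt != target and not store.in_scope(nxt, scope):
                continue
            dist[nxt] = dist[node] + 1
            queue.append(nxt)
    if target not in dist:
        return []
    return [p for p in paths(store, source, target, dist[target], min_weight,
                             expansion_cap, scope) if len(p) == dist[target]]


def is_reciprocal(store: GraphStore, a: int, b: int, min_weight: int = 1) -> bool:
    """True iff connections a→b and b→a both reach *min_weight*."""
    store.get_body(a)
    store.get_body(b)
    ab = store.connections.get((a, b))
    ba = store.connections.get((b, a))
    return bool(ab and ab.weight >= min_weight and ba and ba.weight >= min_weight)


def roi_projection_neurons(
    store: GraphStore,
    roi_from: str,
    roi_to: str,
    min_in: int = 1,
    min_out: int = 1,
) -> list[int]:
    """Neurons projecting from one region to another.

    A neuron projects from *roi_from* to *roi_to* when it receives at least
    *min_in* inputs (post sites) in the source region and makes at least
    *min_out* outputs (pre sites) in the target region.
    """
    for roi in (roi_from, roi_to):
        if roi not in store.roi_hierarchy:
            raise InputError(f"unknown ROI {roi!r}")
    return [
        b
        for b in store.neuron_ids()
        if store.segments[b].roi_post(roi_from) >= min_in
        and store.segments[b].roi_pre(roi_to) >= min_out
    ]


def common_partners(
    store: GraphStore,
    bodies: set[int] | list[int],
    direction: Direction,
    min_weight: int = 1,
    scope: str = "neurons",
) -> list[CommonPartnerRow]:
    """Partners connected (≥ *min_weight*, in *direction*) to every listed body."""
    bodies = sorted(set(bodies))
    if not bodies:
        raise InputError("common_partners requires at least one body")
    per_body: list[dict[int, int]] = []
    for b in bodies:
        per_body.append({
            row.partner_body: row.weight
            for row in partners(store, b, direction, min_weight, scope)
        })
    shared = set(per_body[0])
    for d in per_body[1:]:
        shared &= set(d)
    rows = [
        CommonPartnerRow(p, {b: per_body[i][p] for i, b in enumerate(bodies)})
        for p in shared
    ]
    rows.sort(key=lambda r: (-r.total, r.partner_body))
    return rows


def _roi_profile(store: GraphStore, body: int, leaf_order: list[str]) -> np.ndarray:
    rec = store.segments[body]
    vec = np.array(
        [rec.roi_pre(r) for r in leaf_order] + [rec.roi_post(r) for r in leaf_order],
        dtype=float,
    )
    return vec


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def similar_by_roi_profile(
    store: GraphStore, body: int, top_k: int
) -> list[tuple[int, float]]:
    """Neurons whose regional input/output footprint resembles *body*'s.

    The profile is the concatenated per-leaf-ROI pre and post tallies,
    compared by cosine similarity (so it is scale-invariant: two neurons
    with proportional footprints score 1.0).  The queried body is excluded
    from its own ranking; ties break by body id.
    """
    rec = store.get_body(body)
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    leaf_order = sorted(store.roi_hierarchy.leaves)
    me = _roi_profile(store, body, leaf_order)
    if rec.pre_count + rec.post_count == 0 or not np.any(me):
        raise UndefinedMetricError(
            f"body {body} has no synapses in any leaf ROI; profile undefined"
        )
    scored = []
    for other in store.neuron_ids():
        if other == body:
            continue
        sim = _cosine(me, _roi_profile(store, other, leaf_order))
        scored.append((other, sim))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_k]


def cell_type_summary(
    store: GraphStore, type_name: str
) -> tuple[list[int], np.ndarray]:
    """Members of a cell type and their pairwise connectivity similarity.

    Each member's connectivity vector indexes total weight by (direction,
    partner cell type); untyped partners are pooled under one bin.  The
    similarity matrix is cosine-based, symmetric, with unit diagonal.
    """
    members = [b for b in store.bodies_of_type(type_name) if store.segments[b].is_neuron]
    if not members:
        raise NotFoundError(f"no neuron has cell type {type_name!r}")
    keys: dict[tuple[str, str], int] = {}
    raw: list[Counter] = []
    for b in members:
        vec: Counter = Counter()
        for direction in ("outgoing", "incoming"):
            for row in partners(store, b, direction, min_weight=1, scope="segments"):
                key = (direction, row.partner_type or "(untyped)")
                keys.setdefault(key, len(keys))
                vec[key] += row.weight
        raw.append(vec)
    dim = max(len(keys), 1)
    mat = np.zeros((len(members), dim))
    for i, vec in enumerate(raw):
        for key, w in vec.items():
            mat[i, keys[key]] = w
    sim = np.eye(len(members))
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            sim[i, j] = sim[j, i] = _cosine(mat[i], mat[j])
    return members, sim


def roi_connectivity_matrix(
    store: GraphStore, mode: str = "count"
) -> dict[tuple[str, str], float]:
    """Region-to-region connectivity over leaf ROIs.

    ``count`` mode: entry (a, b) is the number of neurons projecting from a
    to b (inputs in a, outputs in b).  ``weighted`` mode: each neuron
    contributes its input share in a times its output count in b,
    Σ_n (post_n(a)/total_post_n) × pre_n(b), skipping neurons with no
    inputs.  Zero entries are omitted.
    """
    if mode not in ("count", "weighted"):
        raise InputError(f"unknown mode {mode!r}")
    leaves = sorted(store.roi_hierarchy.leaves)
    out: dict[tuple[str, str], float] = {}
    if mode == "count":
        for a in leaves:
            for b in leaves:
                n = len(roi_projection_neurons(store, a, b, 1, 1))
                if n:
                    out[(a, b)] = float(n)
        return out
    for body in store.neuron_ids():
        rec = store.segments[body]
        if rec.post_count == 0:
            continue
        for a in leaves:
            share = rec.roi_post(a) / rec.post_count
            if share == 0.0:
                continue
            for b in leaves:
                w = share * rec.roi_pre(b)
                if w:
                    out[(a, b)] = out.get((a, b), 0.0) + w
    return out


def count_types_matching(store: GraphStore, pattern: str) -> int:
    """Number of neurons whose cell type matches the regex (full match)."""
    pat = _compile(pattern)
    assert pat is not None
    return sum(
        1
        for b in store.neuron_ids()
        if store.segments[b].type and pat.fullmatch(store.segments[b].type)
    )
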