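"""In-memory property-graph store for connectome data.

The store keeps four levels of detail, mirroring how reconstructed EM
volumes are analysed in practice:

* **synapse sites** — individual presynaptic elements (T-bars) and
  postsynaptic densities (PSDs), each with a 3D voxel location, a
  prediction confidence, and boolean membership in every containing ROI;
* **links** — directed pre→post pairings between sites.  Fly synapses are
  polyadic: one pre site may drive many post sites, but each post site has
  at most one presynaptic partner;
* **segments / neurons** — reconstructed bodies owning sites.  Automatic
  segmentation yields a bimodal size distribution: a few large bodies that
  are real neurons and a long tail of tiny fragments.  Large bodies are
  explicitly *designated* neurons so that typical queries can ignore the
  fragment tail;
* **connections and synapse sets** — redundant aggregates.  A
  :class:`Connection` stores the total weight and per-ROI breakdown of a
  directed body pair so that the common queries never have to traverse
  individual synapses; a synapse set groups one body's sites participating
  in one directed connection.

All aggregates are derivable from sites+links; the store maintains them
eagerly and the test-suite checks them against brute-force recomputation.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Sequence

from .errors import InputError, NotFoundError
from .rois import RoiHierarchy

Direction = Literal["outgoing", "incoming"]
SiteKind = Literal["pre", "post"]

#: per-ROI tally: {"pre": int, "post": int}
RoiInfo = dict[str, dict[str, int]]


@dataclass
class SynapseSite:
    """One pre- or post-synaptic element.

    ``rois`` is closed under the hierarchy's ancestor relation: if a leaf
    region is present, all its ancestors are too.
    """

    site_id: int
    kind: SiteKind
    x: int
    y: int
    z: int
    confidence: float
    body_id: int
    rois: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise InputError(
                f"site {self.site_id}: confidence {self.confidence} outside [0, 1]"
            )
        if self.kind not in ("pre", "post"):
            raise InputError(f"site {self.site_id}: kind must be 'pre' or 'post'")

    @property
    def coord(self) -> tuple[int, int, int]:
        return (self.x, self.y, self.z)


class SynapseLink(NamedTuple):
    """A directed pre-site → post-site pairing (one PSD's driver)."""

    pre_site: int
    post_site: int


@dataclass
class SegmentRecord:
    """A reconstructed body: either a tiny fragment or a designated neuron."""

    body_id: int
    instance: str | None = None
    type: str | None = None
    status: str | None = None
    size: int = 0
    pre_count: int = 0
    post_count: int = 0
    roi_info: RoiInfo = field(default_factory=dict)
    is_neuron: bool = False
    dataset: str = ""

    def roi_pre(self, roi: str) -> int:
        return self.roi_info.get(roi, {}).get("pre", 0)

    def roi_post(self, roi: str) -> int:
        return self.roi_info.get(roi, {}).get("post", 0)


@dataclass(frozen=True)
class SynapseSetRecord:
    """The sites of *owner_body* participating in one directed connection."""

    owner_body: int
    partner_body: int
    direction: Direction
    site_ids: frozenset[int]


@dataclass
class Connection:
    """Aggregated directed edge between two bodies.

    ``weight`` counts pre→post links between the bodies (equivalently, the
    number of the target's PSDs driven by the source).  ``roi_info`` gives
    the regional breakdown: ``post`` counts the connection's post sites in
    each ROI, ``pre`` its distinct participating pre sites.
    """

    pre_body: int
    post_body: int
    weight: int
    roi_info: RoiInfo = field(default_factory=dict)


@dataclass
class MetaRecord:
    """Top-level information about one dataset snapshot."""

    dataset: str
    version: str = "1.0"
    total_pre: int = 0
    total_post: int = 0
    last_modified: str = ""


@dataclass(frozen=True)
class PromotionPredicate:
    """Rule for designating segments as neurons.

    The rule is a disjunction — a body is promoted if its status is set
    (when ``require_status``), or any of the size / pre / post thresholds
    is met — and is therefore monotone: growing a body never demotes it.
    """

    min_size: int = 10**7
    min_pre: int = 2
    min_post: int = 10
    require_status: bool = True

    def matches(self, record: SegmentRecord) -> bool:
        if self.require_status and record.status is not None:
            return True
        return (
            record.size >= self.min_size
            or record.pre_count >= self.min_pre
            or record.post_count >= self.min_post
        )

    def to_jsonable(self) -> dict:
        return {
            "min_size": self.min_size,
            "min_pre": self.min_pre,
            "min_post": self.min_post,
            "require_status": self.require_status,
        }

    @classmethod
    def from_jsonable(cls, data: dict) -> "PromotionPredicate":
        return cls(**data)


DEFAULT_PREDICATE = PromotionPredicate()


def _roi_counts(sites: Iterable[SynapseSite]) -> RoiInfo:
    pre: Counter[str] = Counter()
    post: Counter[str] = Counter()
    for s in sites:
        target = pre if s.kind == "pre" else post
        for r in s.rois:
            target[r] += 1
    info: RoiInfo = {}
    for r in set(pre) | set(post):
        entry = {}
        if pre[r]:
            entry["pre"] = pre[r]
        if post[r]:
            entry["post"] = post[r]
        info[r] = entry
    return info


class GraphStore:
    """Indexed, mutable store for one dataset.

    Single-writer contract: queries between mutations see a consistent
    snapshot.  All list-returning operations order results by body id so
    that output never depends on insertion order.
    """

    GRID_CELL = 128  # voxels per spatial-grid cell edge

    def __init__(
        self,
        dataset: str = "dataset",
        hierarchy: RoiHierarchy | None = None,
        version: str = "1.0",
    ):
        self.dataset = dataset
        self.roi_hierarchy = hierarchy if hierarchy is not None else RoiHierarchy([])
        self.segments: dict[int, SegmentRecord] = {}
        self.sites: dict[int, SynapseSite] = {}
        self.links: list[SynapseLink] = []
        self.connections: dict[tuple[int, int], Connection] = {}
        self.synapse_sets: dict[tuple[int, int, Direction], SynapseSetRecord] = {}
        self.meta = MetaRecord(dataset=dataset, version=version)
        self.promotion_predicate: PromotionPredicate | None = None
        # extensibility hook: extra node kinds keyed by a label string;
        # these never participate in any aggregate.
        self.extra_nodes: dict[str, dict[int, dict]] = {}
        # --- indices ---
        self._sites_by_body: dict[int, set[int]] = defaultdict(set)
        self._links_by_pre_site: dict[int, list[SynapseLink]] = defaultdict(list)
        self._link_by_post_site: dict[int, SynapseLink] = {}
        self._pair_links: dict[tuple[int, int], list[SynapseLink]] = defaultdict(list)
        self._out: dict[int, set[int]] = defaultdict(set)
        self._in: dict[int, set[int]] = defaultdict(set)
        self._by_type: dict[str, set[int]] = defaultdict(set)
        self._grid: dict[tuple[int, int, int], list[int]] = defaultdict(list)

    # ------------------------------------------------------------------
    # population (used by the ingest builder and the edit log)
    # ------------------------------------------------------------------

    def _add_segment(self, record: SegmentRecord) -> None:
        if record.body_id in self.segments:
            raise InputError(f"duplicate body id {record.body_id}")
        record.dataset = self.dataset
        self.segments[record.body_id] = record
        if record.type is not None:
            self._by_type[record.type].add(record.body_id)

    def _remove_segment(self, body_id: int) -> None:
        record = self.segments.pop(body_id)
        if record.type is not None:
            self._by_type[record.type].discard(body_id)

    def _add_site(self, site: SynapseSite) -> None:
        if site.site_id in self.sites:
            raise InputError(f"duplicate site id {site.site_id}")
        self.sites[site.site_id] = site
        self._sites_by_body[site.body_id].add(site.site_id)
        self._grid[self._cell(site.coord)].append(site.site_id)

    def _add_link(self, link: SynapseLink) -> None:
        self.links.append(link)
        self._links_by_pre_site[link.pre_site].append(link)
        self._link_by_post_site[link.post_site] = link

    def _cell(self, coord: Sequence[int]) -> tuple[int, int, int]:
        g = self.GRID_CELL
        return (coord[0] // g, coord[1] // g, coord[2] // g)

    # ------------------------------------------------------------------
    # aggregate maintenance
    # ------------------------------------------------------------------

    def body_sites(self, body_id: int, kind: SiteKind | None = None) -> list[SynapseSite]:
        sites = (self.sites[sid] for sid in self._sites_by_body.get(body_id, ()))
        if kind is None:
            return sorted(sites, key=lambda s: s.site_id)
        return sorted((s for s in sites if s.kind == kind), key=lambda s: s.site_id)

    def links_of_body(self, body_id: int, direction: Direction) -> list[SynapseLink]:
        """All links in which *body_id* participates on the given side."""
        out: list[SynapseLink] = []
        for sid in self._sites_by_body.get(body_id, ()):
            site = self.sites[sid]
            if direction == "outgoing" and site.kind == "pre":
                out.extend(self._links_by_pre_site.get(sid, ()))
            elif direction == "incoming" and site.kind == "post":
                link = self._link_by_post_site.get(sid)
                if link is not None:
                    out.append(link)
        return out

    def recompute_segment_aggregates(self, body_id: int) -> None:
        record = self.segments[body_id]
        sites = [self.sites[sid] for sid in self._sites_by_body.get(body_id, ())]
        record.pre_count = sum(1 for s in sites if s.kind == "pre")
        record.post_count = len(sites) - record.pre_count
        record.roi_info = _roi_counts(sites)

    def recompute_pair(self, pre_body: int, post_body: int) -> None:
        """Rebuild the connection, pair-link index and both synapse sets for one pair."""
        pair = (pre_body, post_body)
        links = [
            link
            for sid in self._sites_by_body.get(pre_body, ())
            if self.sites[sid].kind == "pre"
            for link in self._links_by_pre_site.get(sid, ())
            if self.sites[link.post_site].body_id == post_body
        ]
        if not links:
            self._pair_links.pop(pair, None)
            self.connections.pop(pair, None)
            self.synapse_sets.pop((pre_body, post_body, "outgoing"), None)
            self.synapse_sets.pop((post_body, pre_body, "incoming"), None)
            self._out[pre_body].discard(post_body)
            self._in[post_body].discard(pre_body)
            return
        links.sort()
        self._pair_links[pair] = links
        pre_sites = sorted({l.pre_site for l in links})
        post_sites = [l.post_site for l in links]
        info = _roi_counts(
            [self.sites[s] for s in pre_sites] + [self.sites[s] for s in post_sites]
        )
        self.connections[pair] = Connection(pre_body, post_body, len(links), info)
        self.synapse_sets[(pre_body, post_body, "outgoing")] = SynapseSetRecord(
            pre_body, post_body, "outgoing", frozenset(pre_sites)
        )
        self.synapse_sets[(post_body, pre_body, "incoming")] = SynapseSetRecord(
            post_body, pre_body, "incoming", frozenset(post_sites)
        )
        self._out[pre_body].add(post_body)
        self._in[post_body].add(pre_body)

    def rebuild_aggregates(self) -> None:
        """Recompute every derived quantity from sites+links (idempotent)."""
        self.connections.clear()
        self.synapse_sets.clear()
        self._pair_links.clear()
        self._out.clear()
        self._in.clear()
        pairs = {
            (self.sites[l.pre_site].body_id, self.sites[l.post_site].body_id)
            for l in self.links
        }
        for pre_body, post_body in pairs:
            self.recompute_pair(pre_body, post_body)
        for body_id in self.segments:
            self.recompute_segment_aggregates(body_id)
        self.meta.total_pre = sum(1 for s in self.sites.values() if s.kind == "pre")
        self.meta.total_post = len(self.sites) - self.meta.total_pre

    def promote(self, predicate: PromotionPredicate | None = None) -> int:
        """Designate neurons: set ``is_neuron`` exactly where the predicate holds."""
        if predicate is None:
            predicate = self.promotion_predicate or DEFAULT_PREDICATE
        self.promotion_predicate = predicate
        n = 0
        for record in self.segments.values():
            record.is_neuron = predicate.matches(record)
            n += record.is_neuron
        return n

    # ------------------------------------------------------------------
    # lookups
    # ------------------------------------------------------------------

    def get_body(self, body_id: int) -> SegmentRecord:
        try:
            return self.segments[body_id]
        except KeyError:
            raise NotFoundError(f"body {body_id} not in dataset {self.dataset!r}") from None

    def get_connection(self, pre_body: int, post_body: int) -> Connection | None:
        """The stored aggregate for (pre→post), or ``None`` if unconnected."""
        self.get_body(pre_body)
        self.get_body(post_body)
        return self.connections.get((pre_body, post_body))

    def pair_links(self, pre_body: int, post_body: int) -> list[SynapseLink]:
        return list(self._pair_links.get((pre_body, post_body), ()))

    def neuron_ids(self) -> list[int]:
        return sorted(b for b, r in self.segments.items() if r.is_neuron)

    def bodies_in_scope(self, scope: str) -> list[int]:
        if scope == "neurons":
            return self.neuron_ids()
        if scope == "segments":
            return sorted(self.segments)
        raise InputError(f"unknown scope {scope!r} (expected 'neurons' or 'segments')")

    def in_scope(self, body_id: int, scope: str) -> bool:
        if scope == "segments":
            return body_id in self.segments
        if scope == "neurons":
            rec = self.segments.get(body_id)
            return rec is not None and rec.is_neuron
        raise InputError(f"unknown scope {scope!r} (expected 'neurons' or 'segments')")

    def neurons_matching(
        self,
        *,
        name_regex: str | None = None,
        type_regex: str | None = None,
        status: str | None = None,
        roi_any: Iterable[str] | None = None,
        min_size: int | None = None,
        min_pre: int | None = None,
        min_post: int | None = None,
        scope: str = "neurons",
    ) -> list[SegmentRecord]:
        """Bodies in *scope* satisfying all supplied criteria, body id ascending.

        Regexes use Python's :mod:`re` dialect and must match the whole
        type/instance string (use ``.*`` affixes for substring search).
        ``roi_any`` keeps bodies with a nonzero synapse tally in at least
        one of the listed regions.  Status comparison is case-insensitive.
        """
        name_pat = _compile(name_regex)
        type_pat = _compile(type_regex)
        rois = None
        if roi_any is not None:
            rois = set(roi_any)
            for r in rois:
                if r not in self.roi_hierarchy:
                    raise InputError(f"unknown ROI {r!r}")
        out = []
        for body_id in self.bodies_in_scope(scope):
            rec = self.segments[body_id]
            if name_pat is not None and not (rec.instance and name_pat.fullmatch(rec.instance)):
                continue
            if type_pat is not None and not (rec.type and type_pat.fullmatch(rec.type)):
                continue
            if status is not None and (rec.status or "").lower() != status.lower():
                continue
            if rois is not None and not any(r in rec.roi_info for r in rois):
                continue
            if min_size is not None and rec.size < min_size:
                continue
            if min_pre is not None and rec.pre_count < min_pre:
                continue
            if min_post is not None and rec.post_count < min_post:
                continue
            out.append(rec)
        return out

    def synapses_in_box(
        self, min_corner: Sequence[int], max_corner: Sequence[int]
    ) -> list[SynapseSite]:
        """Sites with ``min <= coord < max`` componentwise, in site-id order.

        Served from a uniform spatial grid rather than a full scan.
        """
        lo = tuple(int(c) for c in min_corner)
        hi = tuple(int(c) for c in max_corner)
        if any(a > b for a, b in zip(lo, hi)):
            raise InputError(f"box min corner {lo} exceeds max corner {hi}")
        if lo == hi or any(a == b for a, b in zip(lo, hi)):
            return []
        g = self.GRID_CELL
        out = []
        for cx in range(lo[0] // g, (hi[0] - 1) // g + 1):
            for cy in range(lo[1] // g, (hi[1] - 1) // g + 1):
                for cz in range(lo[2] // g, (hi[2] - 1) // g + 1):
                    for sid in self._grid.get((cx, cy, cz), ()):
                        s = self.sites[sid]
                        if (
                            lo[0] <= s.x < hi[0]
                            and lo[1] <= s.y < hi[1]
                            and lo[2] <= s.z < hi[2]
                        ):
                            out.append(s)
        out.sort(key=lambda s: s.site_id)
        return out

    def bodies_of_type(self, type_name: str) -> list[int]:
        return sorted(self._by_type.get(type_name, ()))

    def add_extra_node(self, label: str, node_id: int, **properties) -> None:
        """Attach an opaque node of an additional kind (e.g. an organelle).

        Extra nodes are carried by label and id only; they never enter any
        aggregate or query defined by this package.
        """
        self.extra_nodes.setdefault(label, {})[node_id] = dict(properties)

    # ------------------------------------------------------------------
    # comparison
    # ------------------------------------------------------------------

    def equals(self, other: "GraphStore", *, ignore_neuron_flags: bool = False) -> bool:
        """Field-for-field equality of data and aggregates.

        ``last_modified`` is excluded; ``ignore_neuron_flags`` additionally
        masks ``is_neuron`` (useful when comparing across promotions).
        """

        def seg(r: SegmentRecord) -> SegmentRecord:
            return replace(r, is_neuron=False) if ignore_neuron_flags else r

        return (
            self.dataset == other.dataset
            and {b: seg(r) for b, r in self.segments.items()}
            == {b: seg(r) for b, r in other.segments.items()}
            and self.sites == other.sites
            and sorted(self.links) == sorted(other.links)
            and self.connections == other.connections
            and self.synapse_sets == other.synapse_sets
            and (self.meta.total_pre, self.meta.total_post)
            == (other.meta.total_pre, other.meta.total_post)
            and self.roi_hierarchy.to_jsonable() == other.roi_hierarchy.to_jsonable()
        )


def _compile(pattern: str | None) -> re.Pattern | None:
    if pattern is None:
        return None
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise InputError(f"invalid regular expression {pattern!r}: {exc}") from None
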