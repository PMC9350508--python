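"""Raw-bundle ingestion, aggregate building, and lossless export.

A *raw bundle* is the CSV/JSON/SWC file set a reconstruction pipeline
emits:

* ``bodies.csv``      — ``body_id,instance,type,status,size``
* ``synapses.csv``    — ``site_id,body_id,kind,x,y,z,confidence``
* ``links.csv``       — ``pre_site_id,post_site_id``
* ``rois.json``       — list of ``{name, parent, box?}`` region nodes
* ``synapse_rois.csv``— optional explicit leaf memberships ``site_id,roi_name``
* ``skeletons/<body_id>.swc`` — optional morphologies

Files are RFC-4180 CSV with a header row; an empty string denotes an
absent optional value.  Export writes the same schema (plus derived
columns, which the loader ignores) so that export → load → build is the
identity on consistent stores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError, IngestError, InputError
from .model import (
    DEFAULT_PREDICATE,
    GraphStore,
    PromotionPredicate,
    SegmentRecord,
    SynapseLink,
    SynapseSite,
)
from .rois import RoiHierarchy, RoiNode


class MembershipSourceWarning(UserWarning):
    """Both explicit ROI memberships and box geometry supplied; table wins."""


@dataclass
class RawBundle:
    """Validated in-memory form of a raw file set."""

    bodies: pd.DataFrame
    sites: pd.DataFrame
    links: pd.DataFrame
    rois: list[RoiNode]
    site_rois: pd.DataFrame | None = None
    skeletons: dict[int, Path] = field(default_factory=dict)
    dataset: str = "dataset"
    version: str = "1.0"
    predicate: PromotionPredicate | None = None
    #: True when loaded from a store archive (its explicit membership table
    #: is authoritative by construction, so no conflict warning applies)
    archived: bool = False


# ----------------------------------------------------------------------
# loading
# ----------------------------------------------------------------------

_BODY_COLS = ["body_id", "instance", "type", "status", "size"]
_SITE_COLS = ["site_id", "body_id", "kind", "x", "y", "z", "confidence"]
_LINK_COLS = ["pre_site_id", "post_site_id"]


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"missing column(s) {missing}", table=path.name)
    return df


def _to_int(value: str, table: str, row: int, col: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise IngestError(f"column {col!r}: {value!r} is not an integer", table=table, row=row)


def _to_float(value: str, table: str, row: int, col: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise IngestError(f"column {col!r}: {value!r} is not a number", table=table, row=row)


def load_bundle(directory: str | Path, dataset: str | None = None) -> RawBundle:
    """Read and validate a raw bundle from *directory*.

    Referential integrity (links → sites → bodies) is checked up front and
    violations are reported with their table and 0-based data row.
    """
    directory = Path(directory)
    for name in ("bodies.csv", "synapses.csv", "links.csv", "rois.json"):
        if not (directory / name).exists():
            raise IngestError(f"required file {name} not found in {directory}", table=name)
    bodies = _read_table(directory / "bodies.csv", _BODY_COLS)
    sites = _read_table(directory / "synapses.csv", _SITE_COLS)
    links = _read_table(directory / "links.csv", _LINK_COLS)
    rois = RoiHierarchy.from_json((directory / "rois.json").read_text())

    body_ids: set[int] = set()
    for row, raw in enumerate(bodies.itertuples(index=False)):
        b = _to_int(raw.body_id, "bodies.csv", row, "body_id")
        if b in body_ids:
            raise IngestError(f"duplicate body_id {b}", table="bodies.csv", row=row)
        body_ids.add(b)
        _to_int(raw.size or "0", "bodies.csv", row, "size")

    site_kind: dict[int, str] = {}
    for row, raw in enumerate(sites.itertuples(index=False)):
        sid = _to_int(raw.site_id, "synapses.csv", row, "site_id")
        if sid in site_kind:
            raise IngestError(f"duplicate site_id {sid}", table="synapses.csv", row=row)
        b = _to_int(raw.body_id, "synapses.csv", row, "body_id")
        if b not in body_ids:
            raise IngestError(f"site {sid} references unknown body {b}",
                              table="synapses.csv", row=row)
        if raw.kind not in ("pre", "post"):
            raise IngestError(f"site {sid}: kind must be 'pre' or 'post', got {raw.kind!r}",
                              table="synapses.csv", row=row)
        conf = _to_float(raw.confidence or "0", "synapses.csv", row, "confidence")
        if not 0.0 <= conf <= 1.0:
            raise IngestError(f"site {sid}: confidence {conf} outside [0, 1]",
                              table="synapses.csv", row=row)
        for col in ("x", "y", "z"):
            _to_int(getattr(raw, col), "synapses.csv", row, col)
        site_kind[sid] = raw.kind

    posts_seen: set[int] = set()
    for row, raw in enumerate(links.itertuples(index=False)):
        p = _to_int(raw.pre_site_id, "links.csv", row, "pre_site_id")
        q = _to_int(raw.post_site_id, "links.csv", row, "post_site_id")
        for sid, want in ((p, "pre"), (q, "post")):
            if sid not in site_kind:
                raise IngestError(f"link references unknown site {sid}", table="links.csv", row=row)
            if site_kind[sid] != want:
                raise IngestError(
                    f"link expects a {want} site but {sid} is {site_kind[sid]}",
                    table="links.csv", row=row,
                )
        if q in posts_seen:
            raise IngestError(
                f"post site {q} appears in more than one link (a PSD has one driver)",
                table="links.csv", row=row,
            )
        posts_seen.add(q)

    site_rois = None
    sr_path = directory / "synapse_rois.csv"
    if sr_path.exists():
        site_rois = _read_table(sr_path, ["site_id", "roi_name"])
        for row, raw in enumerate(site_rois.itertuples(index=False)):
            sid = _to_int(raw.site_id, "synapse_rois.csv", row, "site_id")
            if sid not in site_kind:
                raise IngestError(f"membership references unknown site {sid}",
                                  table="synapse_rois.csv", row=row)
            if raw.roi_name not in rois:
                raise IngestError(f"unknown ROI {raw.roi_name!r}",
                                  table="synapse_rois.csv", row=row)

    skeletons: dict[int, Path] = {}
    skel_dir = directory / "skeletons"
    if skel_dir.is_dir():
        for f in sorted(skel_dir.glob("*.swc")):
            try:
                skeletons[int(f.stem)] = f
            except ValueError:
                raise IngestError(f"skeleton file {f.name} is not named <body_id>.swc",
                                  table="skeletons")

    version, predicate = "1.0", None
    meta_path = directory / "meta.json"
    archived = meta_path.exists()
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        dataset = dataset or meta.get("dataset")
        version = meta.get("version", version)
        if meta.get("promotion_predicate"):
            predicate = PromotionPredicate.from_jsonable(meta["promotion_predicate"])

    return RawBundle(
        bodies=bodies, sites=sites, links=links, rois=list(rois.nodes.values()),
        site_rois=site_rois, skeletons=skeletons,
        dataset=dataset or "dataset", version=version, predicate=predicate,
        archived=archived,
    )


# ----------------------------------------------------------------------
# ROI assignment
# ----------------------------------------------------------------------

def assign_rois(
    sites: pd.DataFrame,
    roi_spec: RoiHierarchy | Iterable[RoiNode],
    site_roi_table: pd.DataFrame | None = None,
    *,
    warn_on_conflict: bool = True,
) -> dict[int, frozenset[str]]:
    """Compute each site's full ROI membership (leaves plus all ancestors).

    Membership comes from exactly one source: the explicit leaf-membership
    table when supplied, otherwise leaf box geometry.  If both are
    available the table wins and a :class:`MembershipSourceWarning` is
    emitted.  A site inside no leaf gets the empty set.
    """
    hierarchy = roi_spec if isinstance(roi_spec, RoiHierarchy) else RoiHierarchy(roi_spec)
    has_boxes = any(
        hierarchy.nodes[n].box is not None for n in hierarchy.leaves
    )
    out: dict[int, frozenset[str]] = {}
    if site_roi_table is not None:
        if has_boxes and warn_on_conflict:
            warnings.warn(
                "both explicit site-ROI table and leaf box geometry supplied; "
                "the explicit table takes precedence",
                MembershipSourceWarning,
                stacklevel=2,
            )
        leaf_members: dict[int, set[str]] = {}
        for raw in site_roi_table.itertuples(index=False):
            sid = int(raw.site_id)
            if raw.roi_name not in hierarchy:
                raise InputError(f"site {sid} assigned to unknown ROI {raw.roi_name!r}")
            leaf_members.setdefault(sid, set()).add(raw.roi_name)
        for raw in sites.itertuples(index=False):
            sid = int(raw.site_id)
            out[sid] = hierarchy.closure(leaf_members.get(sid, ()))
        return out
    for raw in sites.itertuples(index=False):
        sid = int(raw.site_id)
        out[sid] = hierarchy.membership((int(raw.x), int(raw.y), int(raw.z)))
    return out


# ----------------------------------------------------------------------
# building
# ----------------------------------------------------------------------

def build_aggregates(bundle: RawBundle) -> GraphStore:
    """Materialize a consistent :class:`GraphStore` from a validated bundle.

    Derives connections, synapse sets, per-ROI tallies, pre/post counts and
    meta totals from sites+links.  Rebuilding from the same bundle yields an
    identical store.  If the bundle records a promotion predicate (from a
    store archive), neurons are designated with it.
    """
    hierarchy = RoiHierarchy(bundle.rois)
    memberships = assign_rois(bundle.sites, hierarchy, bundle.site_rois,
                              warn_on_conflict=not bundle.archived)
    store = GraphStore(bundle.dataset, hierarchy, bundle.version)
    for raw in bundle.bodies.itertuples(index=False):
        store._add_segment(
            SegmentRecord(
                body_id=int(raw.body_id),
                instance=raw.instance or None,
                type=raw.type or None,
                status=raw.status or None,
                size=int(raw.size or 0),
            )
        )
    for raw in bundle.sites.itertuples(index=False):
        sid = int(raw.site_id)
        store._add_site(
            SynapseSite(
                site_id=sid,
                kind=raw.kind,
                x=int(raw.x), y=int(raw.y), z=int(raw.z),
                confidence=float(raw.confidence or 0),
                body_id=int(raw.body_id),
                rois=memberships[sid],
            )
        )
    for raw in bundle.links.itertuples(index=False):
        store._add_link(SynapseLink(int(raw.pre_site_id), int(raw.post_site_id)))
    store.rebuild_aggregates()
    if bundle.predicate is not None:
        store.promote(bundle.predicate)
    return store


def promote_neurons(store: GraphStore, predicate: PromotionPredicate = DEFAULT_PREDICATE) -> int:
    """Designate segments satisfying *predicate* as neurons; returns the count."""
    return store.promote(predicate)


# ----------------------------------------------------------------------
# SWC skeletons
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SwcNode:
    node_id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


@dataclass
class Skeleton:
    """Ball-and-stick neuron morphology (SWC tree); node order preserved."""

    nodes: list[SwcNode]
    body_id: int | None = None


def read_swc(text: str, body_id: int | None = None) -> Skeleton:
    """Parse standard SWC: 7 whitespace-separated columns, ``#`` comments.

    Structure tags are carried opaquely.  Parents may be declared before or
    after their children; roots use parent ``-1``.  Cycles, dangling
    parents and malformed rows raise :class:`FormatError` with the 1-based
    line number.
    """
    nodes: list[SwcNode] = []
    lines_of: dict[int, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 7:
            raise FormatError(f"expected 7 columns, got {len(parts)}", line=lineno)
        try:
            node = SwcNode(
                node_id=int(parts[0]), structure=int(parts[1]),
                x=float(parts[2]), y=float(parts[3]), z=float(parts[4]),
                radius=float(parts[5]), parent=int(parts[6]),
            )
        except ValueError as exc:
            raise FormatError(f"malformed SWC row: {exc}", line=lineno) from None
        if node.node_id in lines_of:
            raise FormatError(f"duplicate node id {node.node_id}", line=lineno)
        lines_of[node.node_id] = lineno
        nodes.append(node)
    parent_of = {n.node_id: n.parent for n in nodes}
    for n in nodes:
        if n.parent != -1 and n.parent not in parent_of:
            raise FormatError(
                f"node {n.node_id} references missing parent {n.parent}",
                line=lines_of[n.node_id],
            )
    # cycle detection by walking each chain to a root
    state: dict[int, int] = {}  # 0 in-progress, 1 done
    for n in nodes:
        chain = []
        cur = n.node_id
        while cur != -1 and state.get(cur) != 1:
            if state.get(cur) == 0:
                raise FormatError(f"cycle involving node {cur}", line=lines_of[cur])
            state[cur] = 0
            chain.append(cur)
            cur = parent_of[cur]
        for c in chain:
            state[c] = 1
    return Skeleton(nodes=nodes, body_id=body_id)


def write_swc(skeleton: Skeleton) -> str:
    """Serialize a skeleton; ``read_swc(write_swc(s))`` reproduces *s*."""
    lines = ["# SWC export (id structure x y z radius parent)"]
    for n in skeleton.nodes:
        lines.append(
            f"{n.node_id} {n.structure} {n.x:g} {n.y:g} {n.z:g} {n.radius:g} {n.parent}"
        )
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

def export_bundle(store: GraphStore, out_dir: str | Path) -> list[Path]:
    """Write a store back to the raw-bundle file layout.

    The raw columns round-trip exactly; derived columns (pre/post counts,
    ``roi_info`` as a JSON string, the neuron flag) are included for
    downstream consumers and ignored on re-ingestion.  Explicit leaf
    memberships are exported so membership survives even for stores built
    from a table rather than geometry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    leaves = store.roi_hierarchy.leaves

    bodies_rows = []
    for b in sorted(store.segments):
        r = store.segments[b]
        bodies_rows.append({
            "body_id": b, "instance": r.instance or "", "type": r.type or "",
            "status": r.status or "", "size": r.size,
            "pre": r.pre_count, "post": r.post_count,
            "roi_info": json.dumps(r.roi_info, sort_keys=True),
            "is_neuron": int(r.is_neuron),
        })
    cols = ["body_id", "instance", "type", "status", "size",
            "pre", "post", "roi_info", "is_neuron"]
    path = out_dir / "bodies.csv"
    pd.DataFrame(bodies_rows, columns=cols).to_csv(path, index=False)
    written.append(path)

    site_rows = []
    roi_rows = []
    for sid in sorted(store.sites):
        s = store.sites[sid]
        site_rows.append({
            "site_id": sid, "body_id": s.body_id, "kind": s.kind,
            "x": s.x, "y": s.y, "z": s.z, "confidence": repr(s.confidence),
        })
        for roi in sorted(s.rois & leaves):
            roi_rows.append({"site_id": sid, "roi_name": roi})
    path = out_dir / "synapses.csv"
    pd.DataFrame(site_rows, columns=_SITE_COLS).to_csv(path, index=False)
    written.append(path)

    path = out_dir / "links.csv"
    pd.DataFrame(
        [{"pre_site_id": l.pre_site, "post_site_id": l.post_site}
         for l in sorted(store.links)],
        columns=_LINK_COLS,
    ).to_csv(path, index=False)
    written.append(path)

    path = out_dir / "synapse_rois.csv"
    pd.DataFrame(roi_rows, columns=["site_id", "roi_name"]).to_csv(path, index=False)
    written.append(path)

    path = out_dir / "rois.json"
    path.write_text(store.roi_hierarchy.to_json())
    written.append(path)

    meta = {
        "dataset": store.dataset,
        "version": store.meta.version,
        "total_pre": store.meta.total_pre,
        "total_post": store.meta.total_post,
        "promotion_predicate": (
            store.promotion_predicate.to_jsonable() if store.promotion_predicate else None
        ),
    }
    path = out_dir / "meta.json"
    path.write_text(json.dumps(meta, indent=1))
    written.append(path)
    return written
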