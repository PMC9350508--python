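"""Reconstruction-quality metrics.

Proofreading a segmented EM volume is expensive, so released connectomes
are deliberately incomplete: many synaptic partners are still tiny
unlabelled fragments.  These graph-level metrics quantify that
incompleteness:

* **partner completeness** — for one body, the share of its synaptic links
  whose partner is a designated neuron (or, configurably, a traced one),
  with the full distribution of partner reconstruction statuses;
* **region completeness** — for one ROI, the share of synapse sites owned
  by traced bodies (the body-level share is reported alongside);
* **coverage curves** — how many ranked segments are needed to account for
  a given share of a region's synapses.

Geometry-based checks (synapse-to-skeleton distances and the like) are out
of scope here; they belong to the reconstruction pipeline itself.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import InputError, UndefinedMetricError
from .model import Direction, GraphStore, SiteKind


@dataclass
class CompletenessReport:
    """Completeness of one subject (a body or an ROI).

    ``status_breakdown`` partitions the relevant links or sites by the
    owning/partner body's status (absent statuses pool under ``"(none)"``);
    the counts sum to ``total``.
    """

    subject: str
    fraction_complete: float
    status_breakdown: dict[str, int] = field(default_factory=dict)
    total: int = 0
    body_fraction: float | None = None  # ROI reports: traced share of bodies


def _is_traced(store: GraphStore, body: int) -> bool:
    return (store.segments[body].status or "").lower() == "traced"


def partner_completeness(
    store: GraphStore,
    body: int,
    direction: Direction,
    complete: str = "neuron",
) -> CompletenessReport:
    """How fragmented the inputs or outputs of *body* are.

    Every link of *body* in *direction* is attributed to its partner body's
    reconstruction status.  ``fraction_complete`` is the share of links
    whose partner counts as complete: a designated neuron
    (``complete="neuron"``, the default) or a traced body
    (``complete="traced"``).
    """
    store.get_body(body)
    if complete not in ("neuron", "traced"):
        raise InputError(f"unknown completeness predicate {complete!r}")
    links = store.links_of_body(body, direction)
    if not links:
        raise UndefinedMetricError(f"body {body} has no {direction} links")
    breakdown: Counter[str] = Counter()
    n_complete = 0
    for link in links:
        partner_site = link.post_site if direction == "outgoing" else link.pre_site
        partner = store.sites[partner_site].body_id
        rec = store.segments[partner]
        breakdown[rec.status or "(none)"] += 1
        if complete == "neuron":
            n_complete += rec.is_neuron
        else:
            n_complete += _is_traced(store, partner)
    return CompletenessReport(
        subject=f"body {body} ({direction})",
        fraction_complete=n_complete / len(links),
        status_breakdown=dict(breakdown),
        total=len(links),
    )


def roi_sites(store: GraphStore, roi: str, site_kind: SiteKind | None = None):
    if roi not in store.roi_hierarchy:
        raise InputError(f"unknown ROI {roi!r}")
    return [
        s
        for s in store.sites.values()
        if roi in s.rois and (site_kind is None or s.kind == site_kind)
    ]


def roi_completeness(
    store: GraphStore,
    roi: str,
    site_kind: SiteKind | None = None,
) -> CompletenessReport:
    """Share of a region's synapse sites owned by traced bodies.

    Pre and post sites are pooled unless *site_kind* narrows to one kind.
    ``body_fraction`` reports the companion body-level ratio: of the bodies
    with at least one site in the region, the share that are traced.
    """
    sites = roi_sites(store, roi, site_kind)
    if not sites:
        raise UndefinedMetricError(f"ROI {roi!r} contains no sites"
                                   + (f" of kind {site_kind}" if site_kind else ""))
    breakdown: Counter[str] = Counter()
    n_traced = 0
    bodies = set()
    for s in sites:
        rec = store.segments[s.body_id]
        breakdown[rec.status or "(none)"] += 1
        n_traced += _is_traced(store, s.body_id)
        bodies.add(s.body_id)
    traced_bodies = sum(1 for b in bodies if _is_traced(store, b))
    return CompletenessReport(
        subject=f"ROI {roi}" + (f" ({site_kind})" if site_kind else ""),
        fraction_complete=n_traced / len(sites),
        status_breakdown=dict(breakdown),
        total=len(sites),
        body_fraction=traced_bodies / len(bodies),
    )


def coverage_curve(
    store: GraphStore, roi: str, site_kind: SiteKind
) -> list[tuple[int, float]]:
    """Cumulative synapse coverage by top-ranked segments in a region.

    Segments are ranked by their count of *site_kind* sites in *roi*,
    descending (ties broken by ascending body id).  Entry *k* gives the
    fraction of the region's sites of that kind covered by the top *k*
    segments.  The curve is non-decreasing and ends at exactly 1.0.
    """
    sites = roi_sites(store, roi, site_kind)
    if not sites:
        raise UndefinedMetricError(f"ROI {roi!r} contains no {site_kind} sites")
    per_body: Counter[int] = Counter()
    for s in sites:
        per_body[s.body_id] += 1
    ranked = sorted(per_body.items(), key=lambda kv: (-kv[1], kv[0]))
    total = len(sites)
    curve: list[tuple[int, float]] = []
    cum = 0
    for rank, (_, n) in enumerate(ranked, start=1):
        cum += n
        curve.append((rank, cum / total))
    # the final entry covers everything by construction; pin it to avoid
    # floating-point residue at the boundary
    curve[-1] = (curve[-1][0], 1.0)
    return curve
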