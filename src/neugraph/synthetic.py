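"""Deterministic synthetic connectomes with planted ground truth.

Real segmented EM volumes have a characteristic statistical shape that
this generator reproduces at desk scale:

* **bimodal segment sizes** — a handful of large bodies (the planted
  neurons, tens of megavoxels) and a long tail of tiny fragments (kilo- to
  sub-megavoxel) carrying only a few synapses each;
* **polyadic synapses** — each presynaptic T-bar drives a truncated-
  geometric number of postsynaptic densities;
* **hierarchical ROIs** — a grid of leaf boxes under a single root (an
  optional intermediate level exercises deeper ancestor closure);
* **incomplete tracing** — each planted neuron is marked "Traced" with a
  configurable probability, and a configurable share of postsynaptic
  densities lands on fragments.

Fragment synapse and voxel counts are bounded strictly below the default
promotion thresholds and neuron counts strictly above them, so the planted
neuron set is exactly recoverable — which is what makes planted-value
tests exact.  Identical ``(config, seed)`` produce byte-identical files.

The module also provides :func:`toy`, the small fixed fixture used in the
worked examples throughout the documentation and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InputError
from .ingest import RawBundle
from .rois import RoiNode


class WorldConfig(BaseModel):
    """Parameters of a synthetic world; defaults give a small, fast fixture."""

    model_config = ConfigDict(frozen=True)

    n_neurons: int = Field(default=30, ge=0)
    n_fragments: int = Field(default=120, ge=0)
    roi_grid: tuple[int, int] = (2, 2)  # leaf boxes along x and y
    roi_cell: int = Field(default=512, gt=0)  # voxels per leaf-box edge
    roi_depth: int = Field(default=2, ge=2, le=3)  # 3 inserts a mid level per row
    synapses_per_neuron: float = Field(default=20.0, ge=0)  # mean pre sites
    dispersion: float = Field(default=0.0, ge=0)  # gamma-Poisson overdispersion
    fanout_p: float = Field(default=0.5, gt=0, le=1)  # geometric parameter
    fanout_max: int = Field(default=5, ge=1)
    fragment_site_share: float = Field(default=0.2, ge=0, le=1)
    fragment_sites_max: int = Field(default=3, ge=1, le=9)  # below promotion post floor
    fragment_size_range: tuple[int, int] = (1_000, 100_000)
    neuron_size_range: tuple[int, int] = (20_000_000, 50_000_000)
    traced_fraction: float = Field(default=0.9, ge=0, le=1)
    cell_types: tuple[str, ...] = ("KCa", "KCb", "PN1", "PN2", "MBON")
    type_affinity: float = Field(default=0.3, ge=0, le=1)
    dataset: str = "synthetic"
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self) -> "WorldConfig":
        if self.n_neurons == 0 and self.synapses_per_neuron > 0 and self.n_fragments > 0:
            raise ValueError("a world with synapses needs at least one neuron to own them")
        if self.fragment_size_range[1] >= self.neuron_size_range[0]:
            raise ValueError("fragment sizes must stay below neuron sizes (bimodal split)")
        return self


@dataclass
class GroundTruth:
    """Planted quantities, recomputed from the emitted tables by brute force."""

    weights: dict[tuple[int, int], int]
    neuron_ids: frozenset[int]
    fragment_ids: frozenset[int]
    traced_ids: frozenset[int]
    type_of: dict[int, str]
    pre_counts: dict[int, int]
    post_counts: dict[int, int]
    #: (body_id, leaf ROI name, kind) → site count
    roi_tallies: dict[tuple[int, str, str], int]
    total_pre: int
    total_post: int
    traced_fraction: float
    config: WorldConfig | None = field(default=None, repr=False)


NEURON_ID_BASE = 1_000
FRAGMENT_ID_BASE = 500_000


def _roi_nodes(config: WorldConfig) -> list[RoiNode]:
    gx, gy = config.roi_grid
    cell = config.roi_cell
    nodes = [RoiNode("brain", None)]
    for ix in range(gx):
        parent = "brain"
        if config.roi_depth == 3:
            parent = f"lobe_{ix}"
            nodes.append(RoiNode(parent, "brain"))
        for iy in range(gy):
            box = ((ix * cell, iy * cell, 0), ((ix + 1) * cell, (iy + 1) * cell, cell))
            nodes.append(RoiNode(f"r{ix}_{iy}", parent, box))
    return nodes


def _leaf_of(x: int, y: int, config: WorldConfig) -> str | None:
    gx, gy = config.roi_grid
    ix, iy = x // config.roi_cell, y // config.roi_cell
    if 0 <= ix < gx and 0 <= iy < gy:
        return f"r{ix}_{iy}"
    return None


def generate(config: WorldConfig, out_dir: str | Path | None = None) -> tuple[RawBundle, GroundTruth]:
    """Emit a synthetic raw bundle and its planted ground truth.

    The ground truth (connection weights, per-leaf-ROI tallies, neuron and
    traced sets) is recomputed from the emitted tables with independent
    table arithmetic, so it can serve as an oracle for the store's
    aggregate builder.  When *out_dir* is given the bundle files are also
    written there.
    """
    rng = np.random.default_rng(config.seed)
    gx, gy = config.roi_grid
    cell = config.roi_cell
    extent = np.array([gx * cell, gy * cell, cell])

    neuron_ids = [NEURON_ID_BASE + i for i in range(config.n_neurons)]
    fragment_ids = [FRAGMENT_ID_BASE + i for i in range(config.n_fragments)]
    types = {
        b: config.cell_types[i % len(config.cell_types)]
        for i, b in enumerate(neuron_ids)
    }
    preferred = {
        t: config.cell_types[(i + 1) % len(config.cell_types)]
        for i, t in enumerate(config.cell_types)
    }
    traced = {b: bool(rng.random() < config.traced_fraction) for b in neuron_ids}

    bodies_rows = []
    for i, b in enumerate(neuron_ids):
        t = types[b]
        bodies_rows.append({
            "body_id": b,
            "instance": f"{t}_{i}",
            "type": t,
            "status": "Traced" if traced[b] else "",
            "size": int(rng.integers(*config.neuron_size_range)),
        })
    for b in fragment_ids:
        bodies_rows.append({
            "body_id": b, "instance": "", "type": "", "status": "",
            "size": int(rng.integers(*config.fragment_size_range)),
        })

    by_type: dict[str, list[int]] = {}
    for b, t in types.items():
        by_type.setdefault(t, []).append(b)

    site_rows: list[dict] = []
    link_rows: list[dict] = []
    frag_load = {b: 0 for b in fragment_ids}
    frag_open = list(fragment_ids)
    next_site = 1

    def new_site(body: int, kind: str, coord: np.ndarray) -> int:
        nonlocal next_site
        sid = next_site
        next_site += 1
        site_rows.append({
            "site_id": sid, "body_id": body, "kind": kind,
            "x": int(coord[0]), "y": int(coord[1]), "z": int(coord[2]),
            "confidence": round(float(rng.uniform(0.3, 1.0)), 3),
        })
        return sid

    for b in neuron_ids:
        if config.dispersion > 0:
            lam = rng.gamma(1.0 / config.dispersion,
                            config.synapses_per_neuron * config.dispersion)
        else:
            lam = config.synapses_per_neuron
        n_pre = max(2, int(rng.poisson(lam)))  # ≥2 keeps planted neurons promotable
        for _ in range(n_pre):
            pre_coord = rng.integers(0, extent)
            pre_sid = new_site(b, "pre", pre_coord)
            fanout = min(int(rng.geometric(config.fanout_p)), config.fanout_max)
            for _ in range(fanout):
                # PSDs sit within a small neighbourhood of their T-bar
                post_coord = np.clip(
                    pre_coord + rng.integers(-24, 25, size=3), 0, extent - 1
                )
                if frag_open and rng.random() < config.fragment_site_share:
                    owner = frag_open[int(rng.integers(len(frag_open)))]
                    frag_load[owner] += 1
                    if frag_load[owner] >= config.fragment_sites_max:
                        frag_open.remove(owner)
                elif config.n_neurons > 0:
                    if rng.random() < config.type_affinity and by_type.get(preferred[types[b]]):
                        pool = by_type[preferred[types[b]]]
                    else:
                        pool = neuron_ids
                    owner = pool[int(rng.integers(len(pool)))]
                else:
                    continue
                post_sid = new_site(owner, "post", post_coord)
                link_rows.append({"pre_site_id": pre_sid, "post_site_id": post_sid})

    bodies = pd.DataFrame(bodies_rows,
                          columns=["body_id", "instance", "type", "status", "size"])
    sites = pd.DataFrame(site_rows,
                         columns=["site_id", "body_id", "kind", "x", "y", "z", "confidence"])
    links = pd.DataFrame(link_rows, columns=["pre_site_id", "post_site_id"])
    bundle = RawBundle(
        bodies=bodies, sites=sites, links=links, rois=_roi_nodes(config),
        dataset=config.dataset,
    )
    truth = _ground_truth(bundle, config, frozenset(neuron_ids), frozenset(fragment_ids),
                          frozenset(b for b in neuron_ids if traced[b]), types)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle, truth


def _ground_truth(
    bundle: RawBundle,
    config: WorldConfig,
    neuron_ids: frozenset[int],
    fragment_ids: frozenset[int],
    traced_ids: frozenset[int],
    types: dict[int, str],
) -> GroundTruth:
    """Brute-force recomputation of the planted quantities via table joins."""
    sites, links = bundle.sites, bundle.links
    owner = sites.set_index("site_id")["body_id"]
    weights: dict[tuple[int, int], int] = {}
    if len(links):
        pairs = pd.DataFrame({
            "pre_body": links["pre_site_id"].map(owner),
            "post_body": links["post_site_id"].map(owner),
        })
        weights = {
            (int(a), int(b)): int(n)
            for (a, b), n in pairs.value_counts(["pre_body", "post_body"]).items()
        }
    pre_counts = sites[sites["kind"] == "pre"].groupby("body_id").size().to_dict()
    post_counts = sites[sites["kind"] == "post"].groupby("body_id").size().to_dict()
    roi_tallies: dict[tuple[int, str, str], int] = {}
    for row in sites.itertuples(index=False):
        leaf = _leaf_of(int(row.x), int(row.y), config)
        if leaf is not None:
            key = (int(row.body_id), leaf, row.kind)
            roi_tallies[key] = roi_tallies.get(key, 0) + 1
    return GroundTruth(
        weights=weights,
        neuron_ids=neuron_ids,
        fragment_ids=fragment_ids,
        traced_ids=traced_ids,
        type_of=dict(types),
        pre_counts={int(k): int(v) for k, v in pre_counts.items()},
        post_counts={int(k): int(v) for k, v in post_counts.items()},
        roi_tallies=roi_tallies,
        total_pre=int((sites["kind"] == "pre").sum()),
        total_post=int((sites["kind"] == "post").sum()),
        traced_fraction=config.traced_fraction,
        config=config,
    )


def write_bundle(bundle: RawBundle, out_dir: str | Path) -> list[Path]:
    """Write a bundle's tables to the raw CSV/JSON layout."""
    from .rois import RoiHierarchy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (("bodies.csv", bundle.bodies),
                        ("synapses.csv", bundle.sites),
                        ("links.csv", bundle.links)):
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)
    if bundle.site_rois is not None:
        path = out_dir / "synapse_rois.csv"
        bundle.site_rois.to_csv(path, index=False)
        written.append(path)
    path = out_dir / "rois.json"
    path.write_text(RoiHierarchy(bundle.rois).to_json())
    written.append(path)
    return written


# ----------------------------------------------------------------------
# the TOY fixture
# ----------------------------------------------------------------------

#: readable handles for the TOY fixture's site ids
TOY_SITES = {
    "p1": 1, "p2": 2, "p3": 3, "t1": 4,       # pre sites
    "r1": 11, "r2": 12, "r3": 13, "s1": 14, "q1": 15,  # post sites
}


def toy() -> RawBundle:
    """The fixed three-body worked-example fixture.

    Two traced, typed neurons (100, a Kenyon cell; 200, a projection
    neuron) and one small untraced fragment (300) across two leaf regions
    (``alpha``, ``beta``) under a ``brain`` root.  Body 100 makes a strong
    (weight-3) connection onto 200, a weak polyadic side branch onto the
    fragment, and receives one synapse back from 200.
    """
    S = TOY_SITES
    bodies = pd.DataFrame(
        [
            {"body_id": 100, "instance": "", "type": "KCa", "status": "Traced",
             "size": 20_000_000},
            {"body_id": 200, "instance": "", "type": "PN1", "status": "Traced",
             "size": 30_000_000},
            {"body_id": 300, "instance": "", "type": "", "status": "", "size": 10_000},
        ]
    )
    sites = pd.DataFrame(
        [
            {"site_id": S["p1"], "body_id": 100, "kind": "pre",
             "x": 10, "y": 10, "z": 10, "confidence": 0.9},
            {"site_id": S["p2"], "body_id": 100, "kind": "pre",
             "x": 20, "y": 10, "z": 10, "confidence": 0.7},
            {"site_id": S["p3"], "body_id": 100, "kind": "pre",
             "x": 110, "y": 10, "z": 10, "confidence": 0.4},
            {"site_id": S["t1"], "body_id": 200, "kind": "pre",
             "x": 150, "y": 50, "z": 10, "confidence": 0.9},
            {"site_id": S["r1"], "body_id": 200, "kind": "post",
             "x": 12, "y": 10, "z": 10, "confidence": 0.9},
            {"site_id": S["r2"], "body_id": 200, "kind": "post",
             "x": 120, "y": 10, "z": 10, "confidence": 0.8},
            {"site_id": S["r3"], "body_id": 200, "kind": "post",
             "x": 130, "y": 10, "z": 10, "confidence": 0.6},
            {"site_id": S["s1"], "body_id": 300, "kind": "post",
             "x": 121, "y": 12, "z": 10, "confidence": 0.5},
            {"site_id": S["q1"], "body_id": 100, "kind": "post",
             "x": 160, "y": 50, "z": 10, "confidence": 0.9},
        ]
    )
    links = pd.DataFrame(
        [
            {"pre_site_id": S["p1"], "post_site_id": S["r1"]},
            {"pre_site_id": S["p2"], "post_site_id": S["r2"]},
            {"pre_site_id": S["p2"], "post_site_id": S["s1"]},
            {"pre_site_id": S["p3"], "post_site_id": S["r3"]},
            {"pre_site_id": S["t1"], "post_site_id": S["q1"]},
        ]
    )
    rois = [
        RoiNode("brain", None),
        RoiNode("alpha", "brain", ((0, 0, 0), (100, 100, 100))),
        RoiNode("beta", "brain", ((100, 0, 0), (200, 100, 100))),
    ]
    return RawBundle(bodies=bodies, sites=sites, links=links, rois=rois, dataset="toy")
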