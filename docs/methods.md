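# Methods

## The data model

A reconstructed EM connectome is stored at four coupled levels of detail:

1. **Synapse sites.** Each presynaptic T-bar and each postsynaptic density
   (PSD) is a record with a unique integer id, a kind (`pre`/`post`), an
   integer voxel coordinate, a prediction confidence in [0, 1], the id of
   the body that owns it, and the set of every ROI containing it.
2. **Links.** A link pairs one pre site with one post site. Fly synapses
   are polyadic: a pre site may appear in many links, but each post site
   appears in at most one (a PSD has exactly one driver). This asymmetry
   is enforced at ingest.
3. **Bodies.** Automatic segmentation plus proofreading produces a
   strongly bimodal population: a few large bodies that are biological
   neurons, and a long tail of tiny fragments. All bodies are *segments*;
   those satisfying a configurable **promotion predicate** are
   additionally *designated neurons*. The default predicate promotes a
   body when its status is set, or pre_count ≥ 2, or post_count ≥ 10, or
   size ≥ 10⁷ voxels. The predicate is a disjunction of lower bounds and
   hence monotone: growing a body can never demote it.
4. **Redundant aggregates.** For every ordered body pair with at least one
   link, a `Connection` stores the **weight** — the number of pre→post
   links between the pair, equivalently the number of the target's PSDs
   driven by the source — and a per-ROI breakdown (`roi_info`): post
   tallies by post-site location, pre tallies by distinct participating
   pre sites. Two `SynapseSet`s per connection group the participating
   site ids on each side. Each segment likewise carries pre/post counts
   and per-ROI tallies. These aggregates exist purely so that the common
   queries never traverse individual synapses; every one of them is
   derivable from sites+links, and the test-suite asserts that derivation
   against independent brute-force recomputation.

**Weight semantics.** Counting pre→post link pairs (rather than distinct
pre sites) was chosen because it makes the post-side conservation law
exact: summing a connection's post tallies over leaf ROIs, plus its post
sites outside all leaves, recovers the weight. It also matches the
polyadic structure of fly synapses, where the number of driven PSDs is the
natural measure of strength. Autapses (A→A) are stored like any other
connection; merges can create them.

**ROIs.** Regions form a forest; leaf regions may carry an axis-aligned
box in integer voxels with half-open extents (`min ≤ coord < max`), which
tiles space without double counting at boundaries. Membership is closed
upward: a site in a leaf is in all of the leaf's ancestors. Overlapping
leaf boxes are allowed and simply yield multiple memberships. When both
explicit membership tables and box geometry are supplied at ingest, the
explicit table wins (with a warning outside archive reloads). Per-ROI
tallies are kept as first-class maps in memory and serialized as JSON
strings in exported CSV, because the per-ROI breakdown is a map and plain
tabular formats have no map column type.

**Coordinates.** 0-based integer voxels throughout; all boxes half-open.
Spatial queries are served by a uniform grid (128-voxel cells), checked
against a linear scan in tests.

**Determinism.** Every list-returning operation orders by body id (then
partner id, then weight where relevant); no result depends on insertion
order.

## Queries

Neuron scope is the default for every query, with `scope="segments"` as an
explicit opt-in — users rarely want a list of unnamed fragments back.
Notable contracts:

- `partners(..., min_confidence=t)` recomputes effective weights from the
  individual links (both site confidences must reach `t`) rather than
  trusting the stored aggregate.
- `paths` counts length in hops and returns simple paths only; when source
  equals target, only a direct autapse qualifies (cycles through other
  bodies would revisit the source). Scope constrains intermediate bodies;
  the endpoints are exempt because the caller named them explicitly. A
  deterministic node-expansion cap (default 10⁵) replaces a wall-clock
  timeout so results are reproducible; exceeding it raises rather than
  silently truncating. `shortest_paths` finds the BFS distance first and
  then enumerates paths of exactly that length.
- Similarity metrics are this package's own choices (the operations are
  standard in connectome browsers, the formulas are not): ROI-profile
  similarity is the cosine between concatenated per-leaf-ROI pre/post
  tally vectors (scale-invariant by construction); cell-type similarity is
  the cosine between weight vectors indexed by (direction, partner type),
  untyped partners pooled in one bin.
- The weighted region-to-region matrix credits each neuron with its input
  share in the source region times its output count in the target region,
  Σₙ (postₙ(a)/total postₙ) · preₙ(b) — one defensible reading of "neurons
  that go from one region to another"; the count-mode matrix simply counts
  such neurons.

## QC metrics

- **Partner completeness** partitions one body's links in one direction by
  the partner's reconstruction status and reports the fraction whose
  partner counts as complete. Two predicates are offered because both are
  used in practice: *designated neuron* (default) and *status "traced"*
  (case-insensitive). Zero links raise an undefined-metric error rather
  than reporting 0/0.
- **Region completeness** is the fraction of a region's sites (pre and
  post pooled; a per-kind flag exists) owned by traced bodies. Because
  "percentage of segments that are traced" is also a sensible body-level
  reading, the companion `body_fraction` (traced share of bodies with at
  least one site in the region) is reported alongside.
- **Coverage curves** rank segments by their site count of one kind in a
  region (ties broken by ascending body id) and report cumulative
  fractions. The final value is pinned to exactly 1.0 to avoid
  floating-point residue at the boundary; monotonicity and termination at
  1.0 are asserted property-wise.

## Incremental edits

Edit logs are JSON-lines files of merge / split / set_property events with
strictly increasing sequence numbers. Application is incremental: only the
sites, segment aggregates, and body-pair connections touched by an event
are recomputed, so cost scales with the size of the edited bodies and
their partner sets, not the store. Invariants: total site and link counts
are unchanged by merges and splits; the incremental result is
field-for-field equal to a full rebuild from the correspondingly edited
raw tables (asserted on random logs).

Design points that were genuinely open:

- A split event must state `moved_site_ids` explicitly and may carry
  `moved_size` (voxels transferred to the new body), since voxel counts
  are not derivable from the synapse table; the default is 0.
- Neuron designation is re-evaluated once per applied batch under the
  store's current predicate, not after every event — batch application is
  snapshot-like, and per-event re-promotion would make intermediate states
  observable that no snapshot would ever expose.
- Replaying an already-applied sequence number is a warned no-op, so a log
  can be re-consumed safely after a partial failure; a mid-log failure
  leaves the store at the last successful event and reports its number.

## Synthetic worlds

The generator emulates the statistical shape of a segmented fly-brain
volume at desk scale: bimodal body sizes (fragments 10³–10⁵ voxels,
neurons 2–5×10⁷ by default, the gap enforced by a config validator),
polyadic fan-out (truncated geometric, p = 0.5, max 5 PSDs per T-bar),
mean 20 pre sites per neuron (Poisson, optional gamma-Poisson
overdispersion; floored at 2 so planted neurons stay promotable), a 2×2
grid of 512-voxel leaf boxes under a single root (an optional third level
exercises deeper ancestor closure), PSDs placed within ±24 voxels of
their T-bar, a 0.2 probability that a PSD lands on a fragment (capped at
3 sites per fragment, below the promotion floor), neurons marked "Traced"
independently with probability 0.9, and a mild cell-type affinity (0.3)
that biases each type's outputs toward a preferred partner type. These
defaults were chosen once as a realistic desk-scale caricature and are
fully configurable.

Because fragment sizes and synapse counts are bounded strictly below the
default promotion thresholds and neuron values strictly above, the planted
neuron set is exactly recoverable — promotion tests can be exact rather
than statistical. Emitted ground truth (connection weights, per-leaf
tallies, traced/neuron sets) is recomputed from the emitted tables with
independent table arithmetic, not the store's builder, so it can serve as
an oracle. Identical (config, seed) produce byte-identical files.

What the generator does **not** emulate: reconstruction-scale statistics
(it targets ≤10⁵ sites, not hundreds of millions of nodes), spatially
structured neuron morphology (site placement is uniform, so per-ROI
profiles are flatter than real arborizations), correlated proofreading
status (tracing is i.i.d. per neuron), or orphan pre sites (every
generated PSD has a driver). Passing tests on these worlds therefore
validate the algebra and bookkeeping of the store, not biological realism
of any particular query result.

## Statistical checks

Planted-rate recovery tests compare pooled observed fractions against the
planted traced fraction p within three binomial standard errors. The
binomial unit is the **neuron** (each neuron's traced flag is one i.i.d.
Bernoulli draw); site- and link-level fractions are ratio estimators over
those draws, so unit-level SE is the correct leading-order scale, with a
small clustering inflation from unequal per-neuron synapse counts
(coefficient-of-variation term ≈ 1/mean for Poisson counts). Unit tests
that use few seeds add a small fixed margin for that inflation; the
pooled acceptance checks use 50 seeds (≈1,000 neurons per rate) where the
clustering term is negligible.

## Problem sizes

Randomized suites run on worlds of a few hundred sites (dozens of
neurons, tens of fragments): 100 worlds for the aggregate and equivalence
oracles, 1,000 small digraphs (≤12 bodies, ≤30 connections) for path
enumeration against an independent graph library, 50 random edit logs,
100 export/ingest and 100 SWC round-trips, and 3×50 worlds for
planted-rate recovery. These sizes give the property suites broad
coverage while keeping the full run in tens of seconds.

## Known limitations

- The store is single-writer and in-memory; there is no transaction log,
  no server, and no query language — the Python API and the CLI are the
  interface, and snapshots (exported archives) are the unit of release.
- `neurons_matching` regex filters scan the candidate scope; only exact
  type lookup is index-backed. At desk scale this is well below a
  millisecond; a text index would be the first addition for larger data.
- Connection-level `roi_info` pre tallies count *distinct* pre sites, so
  pre-side tallies do not satisfy a conservation law analogous to the
  post side (one pre site can drive PSDs in several connections); only
  the post-side law is asserted.
- SWC structure tags are carried opaquely; no soma/axon semantics are
  validated.
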