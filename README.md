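# neugraph

Property-graph representation and analysis of electron-microscopy
connectomes: neurons, synapses, and brain regions in one indexed in-memory
store, with the standard connectivity query suite, reconstruction-QC
metrics, CSV/SWC ingestion, and incremental maintenance from proofreading
edit logs.

## Who this is for

Dense EM reconstructions of neural tissue (fly medulla, mushroom body,
hemibrain-style volumes) are released as tables of *bodies* (segments, a
few of which are designated neurons), *synapse sites* (presynaptic T-bars
and postsynaptic densities with 3D locations and prediction confidences),
pre→post *links* (polyadic: one T-bar drives several PSDs), and a
hierarchy of named brain regions (ROIs). Answering routine circuit
questions — who are the strong inputs of this neuron? which neurons
project from region A to region B? how complete is the reconstruction
here? — requires a representation that layers redundant aggregates over
the raw synapse graph. `neugraph` provides that representation as a
self-contained library and CLI: no database server, no network, plain
text formats.

## The model in brief

- **weight(A→B)** = number of pre→post links from body A to body B
  (equivalently, the number of B's PSDs driven by A). Stored per ordered
  pair as a `Connection` with a per-ROI breakdown, alongside
  `SynapseSet`s grouping each side's participating sites.
- **roiInfo** — per-ROI `{pre, post}` tallies stored redundantly on
  segments and connections, with membership closed under the ROI
  hierarchy's ancestor relation, so regional queries never touch
  individual synapses.
- **Neuron designation** — segments satisfying a monotone promotion
  predicate (status set, or pre ≥ 2, or post ≥ 10, or size ≥ 10⁷ voxels
  by default) become neurons; queries default to neuron scope.
- **QC** — partner completeness (share of a body's links whose partner is
  a designated neuron), region completeness (share of a region's synapses
  owned by traced bodies), and segment-coverage curves.
- **Edits** — merge/split/property events from a JSON-lines log are
  applied incrementally, recomputing exactly the affected aggregates;
  the result is field-for-field equal to a full rebuild.

Every aggregate is derivable from sites+links, and the test-suite holds
the store to that: brute-force recomputation, independent path-enumeration
oracles, and round-trip identities on randomized fixtures. See
`docs/methods.md` for the full model, parameter semantics, and design
rationale.

## Worked example

The package ships a small fixed fixture: two traced neurons (100, a
Kenyon cell; 200, a projection neuron) and an untraced fragment (300)
across two leaf regions `alpha` and `beta`. Programmatically:

```python
import neugraph as ng

store = ng.build_aggregates(ng.toy())
store.promote()

ng.partners(store, 100, "outgoing", scope="segments")
# [PartnerRow(partner_body=200, weight=3, ...), PartnerRow(partner_body=300, weight=1, ...)]

ng.partner_completeness(store, 100, "outgoing").fraction_complete
# 0.75          (3 of 4 output links land on designated neurons)

ng.roi_completeness(store, "beta").fraction_complete
# 0.8333...     (5 of 6 synapses in beta belong to traced bodies)

ng.coverage_curve(store, "beta", "post")
# [(1, 0.5), (2, 0.75), (3, 1.0)]
```

The same answers through the CLI, against an on-disk store archive:

```sh
neugraph generate --seed 1 --out raw/        # or bring your own CSVs
neugraph ingest raw/ --out store/ --dataset demo
neugraph query partners --body 100 --direction out --scope segments --store store/
neugraph qc roi-completeness --roi beta --store store/
neugraph apply-log --store store/ --log edits.jsonl
```

`query partners` prints, for the fixture above:

```
partner_body,weight,type,instance,status
200,3,PN1,,Traced
300,1,,,
```

meaning body 200 receives three synaptic contacts from body 100 (the
strong partner, listed first) and fragment 300 receives one.

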