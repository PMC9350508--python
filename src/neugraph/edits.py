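"""Incremental maintenance of store aggregates from reconstruction edits.

Proofreading continuously merges and splits segments.  Rather than
rebuilding the whole store after every edit, this module applies a
file-based log of edit events (JSON lines, one event per line) and
repairs exactly the aggregates each event touches: re-owned sites, the
connections and synapse sets of affected body pairs, per-ROI tallies, and
sizes.  The test-suite checks that the incremental result is
field-for-field identical to a full rebuild from the edited raw data.

Event schema (``edits.jsonl``)::

    {"sequence_number": 1, "action": "merge", "target": 100, "source": 200}
    {"sequence_number": 2, "action": "split", "body": 100, "new_body": 900,
     "moved_site_ids": [7, 8], "moved_size": 10000}
    {"sequence_number": 3, "action": "set_property", "body": 100,
     "key": "status", "value": "Traced"}

Sequence numbers must be strictly increasing; re-applying an
already-applied number is a warned no-op, so a log can be replayed
safely.  Neuron designation is re-evaluated once per applied batch (not
per event), matching snapshot-style consistency.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Literal, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import InputError, NeugraphError
from .model import GraphStore, SegmentRecord

_SETTABLE_KEYS = ("instance", "type", "status")


class LogApplicationError(NeugraphError):
    """A log failed mid-way; the store sits at ``last_applied``."""

    def __init__(self, message: str, last_applied: int | None):
        at = f" (store is at sequence {last_applied})" if last_applied is not None \
            else " (no event was applied)"
        super().__init__(message + at)
        self.last_applied = last_applied


class EditEvent(BaseModel):
    """One reconstruction edit."""

    model_config = ConfigDict(frozen=True)

    sequence_number: int
    action: Literal["merge", "split", "set_property"]
    # merge
    target: int | None = None
    source: int | None = None
    # split
    body: int | None = None
    new_body: int | None = None
    moved_site_ids: tuple[int, ...] | None = None
    moved_size: int = 0
    # set_property
    key: str | None = None
    value: str | None = None

    @model_validator(mode="after")
    def _check_fields(self) -> "EditEvent":
        need = {
            "merge": ("target", "source"),
            "split": ("body", "new_body", "moved_site_ids"),
            "set_property": ("body", "key", "value"),
        }[self.action]
        missing = [f for f in need if getattr(self, f) is None]
        if missing:
            raise ValueError(f"{self.action} event missing field(s) {missing}")
        if self.action == "set_property" and self.key not in _SETTABLE_KEYS:
            raise ValueError(
                f"set_property key must be one of {_SETTABLE_KEYS}, got {self.key!r}"
            )
        return self


def _affected_partners(store: GraphStore, body: int) -> set[int]:
    return set(store._out.get(body, ())) | set(store._in.get(body, ()))


def _repair_pairs(store: GraphStore, firsts: Iterable[int], seconds: Iterable[int]) -> None:
    seconds = set(seconds)
    for a in set(firsts):
        for b in seconds:
            store.recompute_pair(a, b)
            store.recompute_pair(b, a)


def apply_merge(store: GraphStore, target: int, source: int) -> GraphStore:
    """Merge *source* into *target*: re-own its sites, drop its record.

    Links that ran between the two bodies become autapse contributions on
    *target*.  Only aggregates touching the two bodies and their partners
    are recomputed.
    """
    store.get_body(target)
    store.get_body(source)
    if target == source:
        raise InputError(f"cannot merge body {target} into itself")
    touched = (
        _affected_partners(store, source)
        | _affected_partners(store, target)
        | {source, target}
    )
    for sid in list(store._sites_by_body.get(source, ())):
        store.sites[sid].body_id = target
        store._sites_by_body[target].add(sid)
    store._sites_by_body.pop(source, None)
    store.segments[target].size += store.segments[source].size
    store._remove_segment(source)
    _repair_pairs(store, touched, {source, target})
    store.recompute_segment_aggregates(target)
    return store


def apply_split(
    store: GraphStore,
    body: int,
    new_body: int,
    moved_site_ids: Sequence[int],
    moved_size: int = 0,
) -> GraphStore:
    """Split *body*: move the listed sites to a freshly created *new_body*.

    The new body starts with no instance/type/status and receives
    *moved_size* voxels (deducted from the donor, whose voxel count is not
    derivable from the synapse table).
    """
    store.get_body(body)
    if new_body in store.segments:
        raise InputError(f"split target body id {new_body} already exists")
    moved = set(int(s) for s in moved_site_ids)
    owned = store._sites_by_body.get(body, set())
    foreign = moved - owned
    if foreign:
        raise InputError(
            f"split of body {body}: site(s) {sorted(foreign)} are not owned by it"
        )
    store._add_segment(SegmentRecord(body_id=new_body, size=moved_size))
    store.segments[body].size -= moved_size
    for sid in moved:
        store.sites[sid].body_id = new_body
        owned.discard(sid)
        store._sites_by_body[new_body].add(sid)
    # partners reachable through the moved sites are the only pairs affected
    partner_bodies: set[int] = set()
    for sid in moved:
        site = store.sites[sid]
        if site.kind == "pre":
            for link in store._links_by_pre_site.get(sid, ()):
                partner_bodies.add(store.sites[link.post_site].body_id)
        else:
            link = store._link_by_post_site.get(sid)
            if link is not None:
                partner_bodies.add(store.sites[link.pre_site].body_id)
    _repair_pairs(store, partner_bodies | {body, new_body}, {body, new_body})
    store.recompute_segment_aggregates(body)
    store.recompute_segment_aggregates(new_body)
    return store


def apply_set_property(store: GraphStore, body: int, key: str, value: str | None) -> GraphStore:
    """Set instance/type/status on a body (empty value clears it)."""
    rec = store.get_body(body)
    if key not in _SETTABLE_KEYS:
        raise InputError(f"set_property key must be one of {_SETTABLE_KEYS}, got {key!r}")
    if key == "type":
        if rec.type is not None:
            store._by_type[rec.type].discard(body)
        if value:
            store._by_type[value].add(body)
    setattr(rec, key, value or None)
    return store


def apply_event(store: GraphStore, event: EditEvent) -> GraphStore:
    if event.action == "merge":
        return apply_merge(store, event.target, event.source)
    if event.action == "split":
        return apply_split(
            store, event.body, event.new_body, event.moved_site_ids, event.moved_size
        )
    return apply_set_property(store, event.body, event.key, event.value)


def apply_log(store: GraphStore, events: Sequence[EditEvent]) -> GraphStore:
    """Fold an ordered event log into the store.

    Events whose sequence number was already applied are skipped with a
    warning (idempotent replay).  Out-of-order numbers are rejected.  On a
    mid-log failure the store is left at the last successfully applied
    event and a :class:`LogApplicationError` reports its sequence number.
    After the batch, neuron designation is re-evaluated under the store's
    current promotion predicate.
    """
    seqs = [e.sequence_number for e in events]
    if any(b <= a for a, b in zip(seqs, seqs[1:])):
        raise InputError(f"event sequence numbers must be strictly increasing, got {seqs}")
    applied: int | None = getattr(store, "applied_sequence", None)
    for event in events:
        if applied is not None and event.sequence_number <= applied:
            warnings.warn(
                f"event {event.sequence_number} already applied; skipping",
                stacklevel=2,
            )
            continue
        try:
            apply_event(store, event)
        except NeugraphError as exc:
            raise LogApplicationError(
                f"event {event.sequence_number} ({event.action}) failed: {exc}", applied
            ) from exc
        applied = event.sequence_number
        store.applied_sequence = applied
    store.promote()
    return store


# ----------------------------------------------------------------------
# log file I/O
# ----------------------------------------------------------------------

def read_log(path: str | Path) -> list[EditEvent]:
    """Parse an ``edits.jsonl`` file (one JSON event per line)."""
    events = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            events.append(EditEvent.model_validate(json.loads(line)))
        except Exception as exc:
            raise InputError(f"{path}, line {lineno}: {exc}") from None
    return events


def write_log(events: Iterable[EditEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for event in events:
            fh.write(json.dumps(event.model_dump(exclude_none=True)) + "\n")
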