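"""Brain-region (ROI) hierarchy and geometry.

Regions of interest form a forest (usually a single tree rooted at a
whole-volume region).  A synapse is a member of every ROI it lies in, and
because ROIs nest, membership is closed upward: a site inside a leaf region
is also inside all of that leaf's ancestors.  Leaf regions may carry an
axis-aligned box in integer voxel coordinates, with half-open intervals
``min <= coord < max``, which tiles space unambiguously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InputError

Coord = tuple[int, int, int]


@dataclass(frozen=True)
class RoiNode:
    """One region in the hierarchy.

    Parameters
    ----------
    name
        Unique region name.
    parent
        Name of the enclosing region, or ``None`` for a root.
    box
        Optional axis-aligned geometry ``((xmin, ymin, zmin), (xmax, ymax, zmax))``
        in integer voxels, half-open on every axis.
    """

    name: str
    parent: str | None = None
    box: tuple[Coord, Coord] | None = None


class RoiHierarchy:
    """Validated ROI forest with ancestor closure and point membership."""

    def __init__(self, nodes: Iterable[RoiNode]):
        self.nodes: dict[str, RoiNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise InputError(f"duplicate ROI name {node.name!r}")
            if node.box is not None:
                lo, hi = node.box
                if not all(int(a) < int(b) for a, b in zip(lo, hi)):
                    raise InputError(f"ROI {node.name!r} has an empty box {node.box}")
            self.nodes[node.name] = node
        children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise InputError(f"ROI {node.name!r} has unknown parent {node.parent!r}")
                children[node.parent].append(node.name)
        self._children = children
        self.leaves: frozenset[str] = frozenset(n for n, c in children.items() if not c)
        # cycle check: every chain of parents must terminate at a root
        self._ancestors: dict[str, tuple[str, ...]] = {}
        for name in self.nodes:
            chain: list[str] = []
            seen = {name}
            cur = self.nodes[name].parent
            while cur is not None:
                if cur in seen:
                    raise InputError(f"ROI hierarchy contains a cycle through {cur!r}")
                seen.add(cur)
                chain.append(cur)
                cur = self.nodes[cur].parent
            self._ancestors[name] = tuple(chain)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def names(self) -> list[str]:
        return sorted(self.nodes)

    def ancestors(self, name: str) -> tuple[str, ...]:
        """Proper ancestors of *name*, nearest first."""
        if name not in self.nodes:
            raise InputError(f"unknown ROI {name!r}")
        return self._ancestors[name]

    def closure(self, names: Iterable[str]) -> frozenset[str]:
        """The upward closure of a set of region names."""
        out: set[str] = set()
        for name in names:
            out.add(name)
            out.update(self.ancestors(name))
        return frozenset(out)

    def leaves_containing(self, point: Sequence[int]) -> frozenset[str]:
        """Leaf regions whose box contains *point* (half-open test).

        Only leaf geometry participates; interior regions are reached
        through ancestor closure.  Overlapping leaf boxes are allowed and
        yield multiple memberships.
        """
        x, y, z = (int(c) for c in point)
        hits = set()
        for name in self.leaves:
            box = self.nodes[name].box
            if box is None:
                continue
            (x0, y0, z0), (x1, y1, z1) = box
            if x0 <= x < x1 and y0 <= y < y1 and z0 <= z < z1:
                hits.add(name)
        return frozenset(hits)

    def membership(self, point: Sequence[int]) -> frozenset[str]:
        """Full ROI membership of a point: containing leaves plus ancestors."""
        return self.closure(self.leaves_containing(point))

    # ---- serialization -------------------------------------------------

    def to_jsonable(self) -> list[dict]:
        out = []
        for name in sorted(self.nodes):
            node = self.nodes[name]
            entry: dict = {"name": node.name, "parent": node.parent}
            if node.box is not None:
                entry["box"] = {"min": list(node.box[0]), "max": list(node.box[1])}
            out.append(entry)
        return out

    @classmethod
    def from_jsonable(cls, data: Iterable[dict]) -> "RoiHierarchy":
        nodes = []
        for entry in data:
            box = None
            if entry.get("box"):
                box = (tuple(entry["box"]["min"]), tuple(entry["box"]["max"]))
            nodes.append(RoiNode(entry["name"], entry.get("parent"), box))
        return cls(nodes)

    @classmethod
    def from_json(cls, text: str) -> "RoiHierarchy":
        return cls.from_jsonable(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.to_jsonable(), indent=1)
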