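"""Attribute schema, generalization hierarchies, and generalization loss.

Each entity carries numerical attributes ``N = {N_1..N_p}`` (e.g. age) and
categorical attributes ``C = {C_1..C_q}`` (e.g. gender, marital status, zip
code).  Publishing a cluster ``s_j`` replaces each member's values by the
cluster's *generalization* ``gen(s_j)``: the [min, max] interval per
numerical attribute and the lowest common ancestor (LCA) in a rooted
value-generalization hierarchy per categorical attribute.

The information sacrificed by that replacement is the **generalization
loss**

    GLoss(G, PS) = sum_j |s_j| * (Attr(s_j, N) + Cate(s_j, C)) / (n (p + q))

with per-cluster factors

    Attr(s_j, N) = sum_k size(gen(s_j)[N_k]) / (global max_k - global min_k)
    Cate(s_j, C) = sum_k height(subtree at LCA of s_j's C_k values)
                         / height(H_Ck)

Both factors are 0 for a fully specific cluster and p (resp. q) for one
generalized to the full range / the hierarchy roots, so GLoss lies in
[0, 1] for every partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import InputError, PreconditionError, ValidationError


# --------------------------------------------------------------------- #
# hierarchies
# --------------------------------------------------------------------- #


class Hierarchy:
    """Rooted tree of category labels; leaves are publishable raw values.

    Built from nested dicts ``{root: {child: {...}}}`` (leaves are empty
    dicts), the JSON interchange form.  Labels must be unique across the
    tree so that a data value resolves to exactly one node.
    """

    def __init__(self, tree: Mapping[str, Mapping]) -> None:
        if len(tree) != 1:
            raise InputError(
                f"hierarchy must have exactly one root, got {len(tree)}"
            )
        self.root: str = next(iter(tree))
        self._parent: dict[str, str | None] = {}
        self._children: dict[str, list[str]] = {}
        stack: list[tuple[str, Mapping, str | None]] = [
            (self.root, tree[self.root], None)
        ]
        while stack:
            label, sub, parent = stack.pop()
            label = str(label)
            if label in self._parent:
                raise InputError(f"duplicate label in hierarchy: {label!r}")
            self._parent[label] = parent
            self._children[label] = [str(c) for c in sub]
            for child in sub:
                stack.append((str(child), sub[child], label))
        self._subtree_height: dict[str, int] = {}
        self._compute_heights(self.root)
        if self.height < 1:
            raise InputError("hierarchy height must be >= 1")

    def _compute_heights(self, label: str) -> int:
        kids = self._children[label]
        h = 1 + max((self._compute_heights(c) for c in kids), default=-1)
        self._subtree_height[label] = h
        return h

    # -- queries ------------------------------------------------------- #

    def __contains__(self, label: object) -> bool:
        return str(label) in self._parent

    @property
    def height(self) -> int:
        """Longest root-to-leaf edge count of the whole tree."""
        return self._subtree_height[self.root]

    @property
    def leaves(self) -> list[str]:
        return [l for l, kids in self._children.items() if not kids]

    def is_leaf(self, label: str) -> bool:
        self._check(label)
        return not self._children[str(label)]

    def subtree_height(self, label: str) -> int:
        """Height of the subtree rooted at ``label`` (0 for a leaf)."""
        self._check(label)
        return self._subtree_height[str(label)]

    def path_from_root(self, label: str) -> list[str]:
        self._check(label)
        path, cur = [], str(label)
        while cur is not None:
            path.append(cur)
            cur = self._parent[cur]
        return path[::-1]

    def ancestor(self, label: str, steps_up: int) -> str:
        """Walk ``steps_up`` levels toward the root (capped at the root)."""
        cur = str(label)
        self._check(cur)
        for _ in range(steps_up):
            parent = self._parent[cur]
            if parent is None:
                break
            cur = parent
        return cur

    def lca(self, values: Iterable[str]) -> str:
        """Deepest node that is an ancestor-or-self of every value."""
        paths = [self.path_from_root(v) for v in values]
        if not paths:
            raise PreconditionError("lca of an empty value set")
        deepest = paths[0]
        depth = len(deepest)
        for p in paths[1:]:
            depth = min(depth, len(p))
            while deepest[:depth][depth - 1] != p[depth - 1]:
                depth -= 1
        return deepest[depth - 1]

    def _check(self, label: str) -> None:
        if str(label) not in self._parent:
            raise InputError(f"unknown hierarchy label: {label!r}")

    # -- constructors -------------------------------------------------- #

    @classmethod
    def flat(cls, leaves: Sequence[str], root: str = "*") -> "Hierarchy":
        """Height-1 tree: every raw value hangs directly off the root."""
        return cls({root: {str(l): {} for l in leaves}})

    @classmethod
    def prefix(
        cls, values: Iterable[str], prefix_len: int = 3, root: str = "*"
    ) -> "Hierarchy":
        """Three-level code tree: full code -> ``prefix_len``-digit prefix
        -> root.  The default shape used for zip codes."""
        tree: dict[str, dict] = {}
        for v in sorted({str(v) for v in values}):
            tree.setdefault(v[:prefix_len], {})[v] = {}
        return cls({root: tree})


def lca(h: Hierarchy, values: Iterable[str]) -> str:
    """Module-level alias for :meth:`Hierarchy.lca`."""
    return h.lca(values)


# --------------------------------------------------------------------- #
# schema and records
# --------------------------------------------------------------------- #


@dataclass
class AttributeSchema:
    """Ordered numerical names plus categorical names bound to hierarchies."""

    numerical: list[str]
    categorical: dict[str, Hierarchy]

    def __post_init__(self) -> None:
        names = list(self.numerical) + list(self.categorical)
        if not names:
            raise InputError("schema needs at least one attribute")
        if len(set(names)) != len(names):
            raise InputError("attribute names must be unique across the schema")

    @property
    def p(self) -> int:
        return len(self.numerical)

    @property
    def q(self) -> int:
        return len(self.categorical)


@dataclass
class NodeRecord:
    """One entity's attribute values (plus untouched sensitive columns)."""

    id: str
    values: dict[str, object]
    sensitive: dict[str, object] = field(default_factory=dict)

    def numeric(self, attr: str) -> float:
        return float(self.values[attr])  # type: ignore[arg-type]

    def category(self, attr: str) -> str:
        return str(self.values[attr])

    def validate(self, schema: AttributeSchema) -> None:
        for attr in schema.numerical:
            if attr not in self.values:
                raise InputError(f"record {self.id}: missing value for {attr!r}")
            v = self.numeric(attr)
            if not math.isfinite(v):
                raise InputError(
                    f"record {self.id}: non-finite value for {attr!r}"
                )
        for attr, h in schema.categorical.items():
            if attr not in self.values:
                raise InputError(f"record {self.id}: missing value for {attr!r}")
            label = self.category(attr)
            if label not in h or not h.is_leaf(label):
                raise InputError(
                    f"record {self.id}: value {label!r} for {attr!r} is not a "
                    "leaf of its hierarchy"
                )


@dataclass(frozen=True)
class GeneralizedRecord:
    """Published form of a cluster: intervals and hierarchy nodes."""

    intervals: dict[str, tuple[float, float]]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        for attr, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValidationError(f"interval for {attr!r} has lo > hi")


# --------------------------------------------------------------------- #
# generalization and loss factors
# --------------------------------------------------------------------- #


def generalize_cluster(
    records: Sequence[NodeRecord], schema: AttributeSchema
) -> GeneralizedRecord:
    """[min, max] per numerical attribute, LCA per categorical attribute."""
    if not records:
        raise PreconditionError("generalize_cluster: empty cluster")
    intervals = {
        attr: (
            min(r.numeric(attr) for r in records),
            max(r.numeric(attr) for r in records),
        )
        for attr in schema.numerical
    }
    categories = {
        attr: h.lca([r.category(attr) for r in records])
        for attr, h in schema.categorical.items()
    }
    return GeneralizedRecord(intervals, categories)


def interval_size(interval: tuple[float, float]) -> float:
    lo, hi = interval
    return hi - lo


def global_ranges(
    records: Iterable[NodeRecord], schema: AttributeSchema
) -> dict[str, tuple[float, float]]:
    """Dataset-wide [min, max] per numerical attribute (the Attr denominator).

    Computed once over the entire input before clustering.
    """
    recs = list(records)
    if not recs:
        raise PreconditionError("global_ranges: no records")
    return {
        attr: (
            min(r.numeric(attr) for r in recs),
            max(r.numeric(attr) for r in recs),
        )
        for attr in schema.numerical
    }


def attr_loss_factor(
    cluster: Sequence[NodeRecord],
    schema: AttributeSchema,
    ranges: Mapping[str, tuple[float, float]],
) -> float:
    """Attr(s_j, N): summed normalized interval widths of the cluster.

    An attribute whose global range is zero contributes 0 — every cluster is
    already fully specific on it.
    """
    gen = generalize_cluster(cluster, schema)
    total = 0.0
    for attr in schema.numerical:
        span = interval_size(ranges[attr])
        if span > 0:
            total += interval_size(gen.intervals[attr]) / span
    return total


def cate_loss_factor(
    cluster: Sequence[NodeRecord], schema: AttributeSchema
) -> float:
    """Cate(s_j, C): summed normalized LCA subtree heights."""
    gen = generalize_cluster(cluster, schema)
    return sum(
        h.subtree_height(gen.categories[attr]) / h.height
        for attr, h in schema.categorical.items()
    )


def generalization_loss(
    partition,
    records: Mapping[str, NodeRecord],
    schema: AttributeSchema,
    ranges: Mapping[str, tuple[float, float]],
) -> float:
    """GLoss(G, PS) over a partition (any object with ``.clusters`` or an
    iterable of id collections)."""
    clusters = getattr(partition, "clusters", partition)
    clusters = [tuple(str(v) for v in c) for c in clusters]
    seen: set[str] = set()
    for c in clusters:
        if seen & set(c):
            raise ValidationError("partition clusters overlap")
        seen |= set(c)
    if seen != set(records):
        raise ValidationError("partition does not cover the record set")
    n = len(records)
    total = 0.0
    for c in clusters:
        recs = [records[v] for v in c]
        total += len(recs) * (
            attr_loss_factor(recs, schema, ranges)
            + cate_loss_factor(recs, schema)
        )
    return total / (n * (schema.p + schema.q))
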