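"""Structure loss of a masked network, its analytic bounds, and total loss.

Collapsing a partition ``PS = {s_1..s_m}`` into supernodes publishes only
*edge counts*: ``|E_sj|`` inside each cluster and ``|E_si,sj|`` between each
cluster pair.  The uncertainty this introduces is the **structure loss**

    SLoss(G, PS) = [ sum_j intraSL(s_j) + sum_{i<j} interSL(s_i, s_j) ]
                   / ( n (n - 1) / 4 )

    intraSL(s_j)      = 2 |E_sj| (1 - |E_sj| / C(|s_j|, 2))
    interSL(s_i, s_j) = 2 |E_si,sj| (1 - |E_si,sj| / (|s_i| |s_j|))

Each term vanishes when the published count pins the edge set down exactly
(no edges, or all possible edges) and peaks when half the possible edges are
present.  ``n`` is the total node count of the graph.

Two published bounds are exposed verbatim: the intra bound
``sum_j |s_j|(|s_j|-1)/4`` (the real-valued maximum of intraSL) and the
inter bound ``sum_{i<j} |s_i||s_j|/4``.  The latter disagrees with the
formulas above — maximizing interSL over the edge count gives
``|s_i||s_j|/2`` — so the derived value is exposed separately and is the
one used for sanity checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import PreconditionError, ValidationError
from .graph import SocialGraph


# --------------------------------------------------------------------- #
# partitions
# --------------------------------------------------------------------- #


@dataclass(frozen=True)
class Partition:
    """Disjoint non-empty clusters s_1..s_m covering the node set."""

    clusters: tuple[tuple[str, ...], ...]

    def __init__(self, clusters: Iterable[Iterable[str]]) -> None:
        clusters = tuple(tuple(str(v) for v in c) for c in clusters)
        object.__setattr__(self, "clusters", clusters)
        if not clusters:
            raise ValidationError("partition must have at least one cluster")
        seen: set[str] = set()
        for c in clusters:
            if not c:
                raise ValidationError("empty cluster in partition")
            cs = set(c)
            if len(cs) != len(c):
                raise ValidationError("duplicate node inside a cluster")
            if seen & cs:
                raise ValidationError("partition clusters overlap")
            seen |= cs
        object.__setattr__(self, "_members", frozenset(seen))

    @property
    def m(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def members(self) -> frozenset[str]:
        return self._members  # type: ignore[attr-defined]

    def validate_cover(self, node_ids: Iterable[str]) -> None:
        ids = {str(v) for v in node_ids}
        if self.members != ids:
            missing = ids - self.members
            extra = self.members - ids
            raise ValidationError(
                f"partition does not cover node set (missing {sorted(missing)[:5]}, "
                f"extra {sorted(extra)[:5]})"
            )


# --------------------------------------------------------------------- #
# edge counts
# --------------------------------------------------------------------- #


def intra_edges(g: SocialGraph, s: Iterable[str]) -> int:
    """|E_s|: unordered linked pairs inside cluster ``s``."""
    idx = [g.index(v) for v in s]
    sub = g.adjacency[np.ix_(idx, idx)]
    return int(sub.sum()) // 2


def inter_edges(g: SocialGraph, si: Iterable[str], sj: Iterable[str]) -> int:
    """|E_si,sj|: edges with one endpoint in each of two disjoint clusters."""
    si, sj = {str(v) for v in si}, {str(v) for v in sj}
    if si & sj:
        raise PreconditionError("inter_edges: clusters overlap")
    ii = [g.index(v) for v in si]
    jj = [g.index(v) for v in sj]
    return int(g.adjacency[np.ix_(ii, jj)].sum())


# --------------------------------------------------------------------- #
# structure loss
# --------------------------------------------------------------------- #


def _intra_sl(e: float, size: int) -> float:
    if size < 2:
        return 0.0
    pairs = size * (size - 1) / 2
    return 2.0 * e * (1.0 - e / pairs)


def _inter_sl(e: float, size_i: int, size_j: int) -> float:
    return 2.0 * e * (1.0 - e / (size_i * size_j))


def intra_structure_loss(g: SocialGraph, s: Iterable[str]) -> float:
    """intraSL(s): 0 for singleton, edgeless, or complete clusters."""
    s = [str(v) for v in s]
    return _intra_sl(intra_edges(g, s), len(s))


def inter_structure_loss(
    g: SocialGraph, si: Iterable[str], sj: Iterable[str]
) -> float:
    """interSL(si, sj) for disjoint clusters."""
    si, sj = [str(v) for v in si], [str(v) for v in sj]
    return _inter_sl(inter_edges(g, si, sj), len(si), len(sj))


def structure_loss(g: SocialGraph, partition: Partition) -> float:
    """SLoss(G, PS), normalized by n(n-1)/4 with n the node count of G."""
    partition.validate_cover(g.node_ids)
    cs = partition.clusters
    total = sum(intra_structure_loss(g, s) for s in cs)
    for i in range(len(cs)):
        for j in range(i + 1, len(cs)):
            total += inter_structure_loss(g, cs[i], cs[j])
    n = g.n
    return total / (n * (n - 1) / 4.0)


def structural_loss_bounds(partition: Partition) -> tuple[float, float]:
    """The published (max_intra, max_inter) bounds, verbatim.

    max_intra = sum_j |s_j|(|s_j|-1)/4 — the real-valued maximum of the
    summed intraSL.  max_inter = sum_{i<j} |s_i||s_j|/4 as published; see
    :func:`derived_inter_bound` for the maximum actually attained by the
    interSL formula.
    """
    sizes = partition.sizes
    max_intra = sum(s * (s - 1) / 4.0 for s in sizes)
    max_inter = sum(
        sizes[i] * sizes[j] / 4.0
        for i in range(len(sizes))
        for j in range(i + 1, len(sizes))
    )
    return max_intra, max_inter


def derived_inter_bound(partition: Partition) -> float:
    """sum_{i<j} |s_i||s_j|/2: the true maximum of the summed interSL."""
    sizes = partition.sizes
    return sum(
        sizes[i] * sizes[j] / 2.0
        for i in range(len(sizes))
        for j in range(i + 1, len(sizes))
    )


def total_loss(gloss: float, sloss: float) -> float:
    """Combined clustering loss: the unweighted sum GLoss + SLoss.

    The trade-off weight ``a`` steers the clustering itself; the report sums
    the two losses on their shared [0, 1] scale.
    """
    return gloss + sloss


# --------------------------------------------------------------------- #
# reports
# --------------------------------------------------------------------- #


@dataclass
class LossReport:
    """Loss evaluation of one clustering run at parameters (k, a)."""

    k: int
    a: float
    gloss: float
    sloss: float
    per_cluster_intra: list[float] = field(default_factory=list)
    per_pair_inter: list[list[float]] = field(default_factory=list)

    @property
    def total(self) -> float:
        return total_loss(self.gloss, self.sloss)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "a": self.a,
            "gloss": self.gloss,
            "sloss": self.sloss,
            "total": self.total,
            "per_cluster_intra": self.per_cluster_intra,
            "per_pair_inter": self.per_pair_inter,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def csv_row(self) -> tuple:
        """Flat row (k, a, gloss, sloss, total) for the sweep CSV."""
        return (self.k, self.a, self.gloss, self.sloss, self.total)


def evaluate_losses(
    g: SocialGraph,
    partition: Partition,
    records,
    schema,
    ranges,
    k: int,
    a: float,
) -> LossReport:
    """Full loss report for one partition (GLoss, SLoss, breakdowns)."""
    from .attributes import generalization_loss  # local import: no cycle

    partition.validate_cover(g.node_ids)
    cs = partition.clusters
    intra = [intra_structure_loss(g, s) for s in cs]
    inter = [
        [
            inter_structure_loss(g, cs[i], cs[j]) if j > i else 0.0
            for j in range(len(cs))
        ]
        for i in range(len(cs))
    ]
    n = g.n
    sloss = (sum(intra) + sum(map(sum, inter))) / (n * (n - 1) / 4.0)
    gloss = generalization_loss(partition, records, schema, ranges)
    if not (0.0 <= sloss <= 1.0 + 1e-12 and 0.0 <= gloss <= 1.0 + 1e-12):
        raise ValidationError(
            f"loss out of range: gloss={gloss}, sloss={sloss}"
        )
    return LossReport(k, a, gloss, min(sloss, 1.0), intra, inter)
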