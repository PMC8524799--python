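"""Greedy k-anonymous clustering of an attributed social network.

Clusters are grown one at a time.  While at least ``k`` nodes remain
unassigned, the unassigned node of maximum degree seeds a new cluster,
which then absorbs, one at a time, the unassigned node of minimal candidate
cost until it holds ``k`` members.  The fewer-than-``k`` leftovers are then
appended, in input order, each to the existing cluster of minimal cost.
Every cluster therefore ends with at least ``k`` members, and the procedure
is deterministic for a fixed input order (all ties break on the smallest
input-file index).

The candidate cost of adding node ``v`` to cluster ``s`` blends the two
information scales with the user weight ``a`` in [0, 1]:

    cost(v, s) = a * (Attr(s+v) + Cate(s+v)) / (p + q)
                 + (1 - a) * D(v, s)

The first term is the would-be generalization factor of the grown cluster,
normalized to [0, 1]; the second is the structure distance.  ``a = 1``
clusters purely on attributes, ``a = 0`` purely on network structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .attributes import (
    AttributeSchema,
    NodeRecord,
    attr_loss_factor,
    cate_loss_factor,
    global_ranges,
)
from .errors import ParameterError, PreconditionError
from .graph import SocialGraph
from .loss import Partition


@dataclass(frozen=True)
class ClusterParams:
    """Anonymity level ``k`` (>= 2) and attribute/structure weight ``a``."""

    k: int
    a: float

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 2:
            raise ParameterError(f"k must be an integer >= 2, got {self.k}")
        if not 0.0 <= self.a <= 1.0:
            raise ParameterError(f"a must lie in [0, 1], got {self.a}")


def seed_node(g: SocialGraph, unassigned: Iterable[str]) -> str:
    """Unassigned node of maximum degree; ties -> smallest input index."""
    pool = [str(v) for v in unassigned]
    if not pool:
        raise PreconditionError("seed_node: no unassigned nodes")
    return min(pool, key=lambda v: (-g.degree(v), g.order_index(v)))


def candidate_cost(
    v: str,
    s: Iterable[str],
    g: SocialGraph,
    records: Mapping[str, NodeRecord],
    schema: AttributeSchema,
    ranges: Mapping[str, tuple[float, float]],
    a: float,
) -> float:
    """Blended cost of growing cluster ``s`` with node ``v``."""
    members = [str(u) for u in s]
    v = str(v)
    if v in members:
        raise PreconditionError(f"candidate_cost: {v!r} already in cluster")
    if not members:
        raise PreconditionError("candidate_cost: empty cluster")
    grown = [records[u] for u in members] + [records[v]]
    attr_term = (
        attr_loss_factor(grown, schema, ranges)
        + cate_loss_factor(grown, schema)
    ) / (schema.p + schema.q)
    return a * attr_term + (1.0 - a) * g.structure_distance(v, members)


def greedy_k_cluster(
    g: SocialGraph,
    records: Mapping[str, NodeRecord],
    schema: AttributeSchema,
    params: ClusterParams,
) -> Partition:
    """Partition the node set into clusters of size >= k (see module doc)."""
    k, a = params.k, params.a
    if k > g.n:
        raise ParameterError(f"k={k} exceeds the node count n={g.n}")
    if set(records) != set(g.node_ids):
        raise PreconditionError("records do not match the graph's node set")
    ranges = global_ranges(records.values(), schema)

    unassigned = set(g.node_ids)
    clusters: list[list[str]] = []
    while len(unassigned) >= k:
        seed = seed_node(g, unassigned)
        unassigned.discard(seed)
        cluster = [seed]
        while len(cluster) < k:
            best = min(
                unassigned,
                key=lambda v: (
                    candidate_cost(v, cluster, g, records, schema, ranges, a),
                    g.order_index(v),
                ),
            )
            unassigned.discard(best)
            cluster.append(best)
        clusters.append(cluster)

    # leftovers (< k of them): absorbed one at a time, in input order,
    # each into its minimal-cost existing cluster (ties -> first cluster)
    for v in sorted(unassigned, key=g.order_index):
        j = min(
            range(len(clusters)),
            key=lambda i: (
                candidate_cost(v, clusters[i], g, records, schema, ranges, a),
                i,
            ),
        )
        clusters[j].append(v)

    return Partition(clusters)


def assert_k_anonymous(partition: Partition, k: int) -> bool:
    """True iff every cluster holds at least ``k`` members."""
    return all(size >= k for size in partition.sizes)
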