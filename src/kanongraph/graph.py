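"""Social-network graph core: adjacency representation and distance measures.

The network is an undirected, unweighted graph ``G = (V, E)`` over ``N``
entities, held as a symmetric binary adjacency matrix ``A = {a_ij}``.

Two dissimilarity measures drive the clustering:

* **node distance** ``D(v_i, v_j) = d / mn`` where ``d`` is the number of
  edges on a shortest ``v_i``–``v_j`` path and ``mn`` the number of nodes on
  that path (``d + 1``), i.e. ``L / (L + 1)`` for hop count ``L``.  The value
  is 0 for a node against itself and approaches 1 for distant nodes; a pair
  in different connected components is assigned the supremum 1.
* **structure distance** ``D(v_i, s)``: the mean node distance from ``v_i``
  to the members of cluster ``s``.

Both measures live in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import InputError, PreconditionError

logger = logging.getLogger(__name__)

INFINITY = float("inf")

#: Distance assigned to a pair of nodes in different connected components.
#: The supremum of L/(L+1), keeping node_distance inside [0, 1].
DISCONNECTED_DISTANCE = 1.0


@dataclass
class SocialGraph:
    """Undirected unweighted graph over opaque string node identifiers.

    Parameters
    ----------
    node_ids
        Ordered, unique entity identifiers.  The order is significant: it is
        the tie-breaking order used by the clustering algorithm.
    adjacency
        ``N x N`` symmetric 0/1 matrix with a zero diagonal.
    """

    node_ids: list[str]
    adjacency: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)
    _hops: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.node_ids = [str(v) for v in self.node_ids]
        a = np.asarray(self.adjacency)
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise InputError("duplicate node identifiers")
        if a.shape != (n, n):
            raise InputError(
                f"adjacency shape {a.shape} does not match {n} node ids"
            )
        if not np.isin(a, (0, 1)).all():
            raise InputError("adjacency entries must be 0 or 1")
        if (a != a.T).any():
            raise InputError("adjacency matrix must be symmetric")
        if np.diagonal(a).any():
            raise InputError("adjacency diagonal must be zero (no self-loops)")
        self.adjacency = a.astype(np.uint8)
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index(self, vid: str) -> int:
        try:
            return self._index[str(vid)]
        except KeyError:
            raise InputError(f"unknown node id: {vid!r}") from None

    def order_index(self, vid: str) -> int:
        """Input-file position of a node; the deterministic tie-break key."""
        return self.index(vid)

    def degree(self, vid: str) -> int:
        return int(self.adjacency[self.index(vid)].sum())

    def edges(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return [(self.node_ids[i], self.node_ids[j]) for i, j in zip(ii, jj)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges())
        return g

    # ------------------------------------------------------------------ #
    # distances
    # ------------------------------------------------------------------ #

    def _hop_matrix(self) -> np.ndarray:
        """All-pairs BFS hop counts; ``inf`` marks disconnected pairs."""
        if self._hops is None:
            hops = np.full((self.n, self.n), INFINITY)
            g = self.to_networkx()
            for src, lengths in nx.all_pairs_shortest_path_length(g):
                i = self._index[src]
                for dst, length in lengths.items():
                    hops[i, self._index[dst]] = length
            self._hops = hops
        return self._hops

    def shortest_path_edges(self, vi: str, vj: str) -> float:
        """Minimum number of edges on any vi-vj path (inf if none)."""
        return float(self._hop_matrix()[self.index(vi), self.index(vj)])

    def node_distance(self, vi: str, vj: str) -> float:
        """L/(L+1) for hop count L; 0 on the diagonal, 1 across components."""
        hops = self.shortest_path_edges(vi, vj)
        if np.isinf(hops):
            return DISCONNECTED_DISTANCE
        return hops / (hops + 1.0)

    def structure_distance(self, vi: str, s: Iterable[str]) -> float:
        """Mean node distance from ``vi`` to the members of cluster ``s``."""
        members = [str(v) for v in s]
        if not members:
            raise PreconditionError("structure_distance: empty cluster")
        if str(vi) in members:
            raise PreconditionError(
                f"structure_distance: node {vi!r} is a member of the cluster"
            )
        i = self.index(vi)
        hops = self._hop_matrix()[i, [self.index(v) for v in members]]
        dists = np.full(hops.shape, DISCONNECTED_DISTANCE)
        finite = np.isfinite(hops)
        dists[finite] = hops[finite] / (hops[finite] + 1.0)
        return float(dists.mean())


def from_edge_list(
    edges: Iterable[tuple[str, str]], node_ids: Sequence[str]
) -> SocialGraph:
    """Build a :class:`SocialGraph` from undirected id pairs.

    Duplicate edges (in either orientation) collapse to one; self-loops are
    dropped with a warning.  Every id in ``edges`` must appear in
    ``node_ids``.
    """
    ids = [str(v) for v in node_ids]
    index = {v: i for i, v in enumerate(ids)}
    if len(index) != len(ids):
        raise InputError("duplicate node identifiers")
    a = np.zeros((len(ids), len(ids)), dtype=np.uint8)
    for u, v in edges:
        u, v = str(u), str(v)
        for w in (u, v):
            if w not in index:
                raise InputError(f"edge references unknown node id: {w!r}")
        if u == v:
            logger.warning("dropping self-loop on node %r", u)
            continue
        a[index[u], index[v]] = 1
        a[index[v], index[u]] = 1
    return SocialGraph(ids, a)
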