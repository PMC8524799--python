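"""Independent naive re-implementation of the distance and loss formulas.

Deliberately written from the defining formulas with plain nested loops and
Floyd–Warshall — no imports from the package — so it can serve as an
oracle for the production implementation.
"""

from __future__ import annotations

import math

INF = math.inf


# --------------------------------------------------------------------- #
# distances (shortest paths via Floyd–Warshall, not BFS)
# --------------------------------------------------------------------- #


def hop_matrix(adj: list[list[int]]) -> list[list[float]]:
    n = len(adj)
    d = [
        [0.0 if i == j else (1.0 if adj[i][j] else INF) for j in range(n)]
        for i in range(n)
    ]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def node_distance(hops: list[list[float]], i: int, j: int) -> float:
    L = hops[i][j]
    return 1.0 if L == INF else L / (L + 1.0)


def structure_distance(hops, i: int, members: list[int]) -> float:
    return sum(node_distance(hops, i, j) for j in members) / len(members)


# --------------------------------------------------------------------- #
# generalization loss, with an ancestor-walk LCA over raw nested dicts
# --------------------------------------------------------------------- #


def _paths(tree: dict, prefix=()) -> dict:
    """label -> root path, computed directly from the nested-dict tree."""
    out = {}
    for label, sub in tree.items():
        path = prefix + (label,)
        out[label] = path
        out.update(_paths(sub, path))
    return out


def _depth_of_deepest_leaf(tree: dict) -> int:
    return 1 + max(
        (_depth_of_deepest_leaf(sub) for sub in tree.values()), default=-1
    )


def _subtree(tree: dict, label: str):
    for lab, sub in tree.items():
        if lab == label:
            return {lab: sub}
        found = _subtree(sub, label)
        if found is not None:
            return found
    return None


def gloss(
    clusters: list[list[int]],
    ages: list[float],
    cats: dict[str, list[str]],
    trees: dict[str, dict],
) -> float:
    """GLoss from the formulas: one numeric attribute (ages) plus arbitrary
    categorical attributes given as value lists and raw nested-dict trees."""
    n = len(ages)
    p, q = 1, len(cats)
    lo, hi = min(ages), max(ages)
    total = 0.0
    for c in clusters:
        attr = 0.0
        if hi > lo:
            attr = (max(ages[i] for i in c) - min(ages[i] for i in c)) / (
                hi - lo
            )
        cate = 0.0
        for name, values in cats.items():
            tree = trees[name]
            paths = _paths(tree)
            member_paths = [paths[values[i]] for i in c]
            d = min(len(p_) for p_ in member_paths)
            while len({p_[:d] for p_ in member_paths}) > 1:
                d -= 1
            anc = member_paths[0][d - 1]
            height_tree = _depth_of_deepest_leaf(tree) - 1
            sub = _subtree(tree, anc)
            height_anc = _depth_of_deepest_leaf(sub) - 1
            cate += height_anc / height_tree
        total += len(c) * (attr + cate)
    return total / (n * (p + q))


# --------------------------------------------------------------------- #
# structure loss
# --------------------------------------------------------------------- #


def sloss(adj: list[list[int]], clusters: list[list[int]]) -> float:
    n = len(adj)

    def intra(c):
        e = sum(adj[i][j] for i in c for j in c if i < j)
        pairs = len(c) * (len(c) - 1) / 2
        return 0.0 if pairs == 0 else 2 * e * (1 - e / pairs)

    def inter(ci, cj):
        e = sum(adj[i][j] for i in ci for j in cj)
        return 2 * e * (1 - e / (len(ci) * len(cj)))

    total = sum(intra(c) for c in clusters)
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            total += inter(clusters[i], clusters[j])
    return total / (n * (n - 1) / 4)
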