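"""Bundled datasets, synthetic edges, linkage auditing, sweeps, and oracles.

The package ships three small datasets as plain CSV:

* a 60-patient medical record table (the clustering benchmark; one
  numerical attribute, Age, and four categorical quasi-identifiers —
  Gender, Marriage, Smoke, Zip code — plus the sensitive Diagnosis);
* a 7-row private hospital table and 6-row public table illustrating a
  quasi-identifier linkage attack;
* two reference 10 x 6 loss grids (generalization and structure loss over
  k = 3..30, a = 0..1) recorded from the original study of that benchmark.

The benchmark's social-network edge list was never published, so a seeded
synthetic generator (Erdős–Rényi or ring lattice with rewiring) stands in
for it; see :func:`synth_edges` and the methods note.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .attributes import (
    AttributeSchema,
    Hierarchy,
    NodeRecord,
    global_ranges,
)
from .clustering import ClusterParams, greedy_k_cluster
from .errors import InputError, ParameterError
from .graph import SocialGraph, from_edge_list
from .loss import (
    LossReport,
    Partition,
    evaluate_losses,
    intra_edges,
    total_loss,
)

QUASI_IDENTIFIERS = ["Gender", "Marriage", "Smoke", "Zip code"]
SENSITIVE_ATTRIBUTE = "Diagnosis"

#: Default sweep grids of the benchmark study.
DEFAULT_K_GRID = [3, 6, 9, 12, 15, 18, 21, 24, 27, 30]
DEFAULT_A_GRID = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]

#: Default mean degree of the synthetic stand-in network (sparse social
#: graphs typically average a handful of contacts per person).
DEFAULT_MEAN_DEGREE = 4.0


def _load_csv(name: str, **kwargs) -> pd.DataFrame:
    text = resources.files("kanongraph.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), **kwargs)


# --------------------------------------------------------------------- #
# bundled datasets
# --------------------------------------------------------------------- #


def benchmark_frame() -> pd.DataFrame:
    """The 60-patient record table as a DataFrame (all columns as strings)."""
    return _load_csv("benchmark_patients.csv", dtype=str)


def benchmark_records() -> list[NodeRecord]:
    """The 60 patient records; Diagnosis rides along as the sensitive
    attribute and never enters the clustering schema."""
    df = benchmark_frame()
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        records.append(
            NodeRecord(
                id=d["id"],
                values={
                    "Age": float(d["Age"]),
                    "Gender": d["Gender"],
                    "Marriage": d["Marriage"],
                    "Smoke": d["Smoke"],
                    "Zip code": d["Zip code"],
                },
                sensitive={SENSITIVE_ATTRIBUTE: d[SENSITIVE_ATTRIBUTE]},
            )
        )
    return records


def benchmark_schema() -> AttributeSchema:
    """Schema of the 60-patient table with the default hierarchies:
    flat trees for Gender/Smoke/Marriage, a 3-level prefix tree for zip."""
    zips = [r.category("Zip code") for r in benchmark_records()]
    return AttributeSchema(
        numerical=["Age"],
        categorical={
            "Gender": Hierarchy.flat(["M", "F"]),
            "Marriage": Hierarchy.flat(["Single", "Marriage", "Divorce"]),
            "Smoke": Hierarchy.flat(["Y", "N"]),
            "Zip code": Hierarchy.prefix(zips),
        },
    )


def benchmark_network(
    seed: int,
    mean_degree: float = DEFAULT_MEAN_DEGREE,
    model: str = "er",
) -> SocialGraph:
    """Seeded synthetic social network over the 60 patient ids."""
    records = benchmark_records()
    edges = synth_edges(len(records), mean_degree, model, seed)
    return from_edge_list(edges, [r.id for r in records])


def link_attack_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(private 7-row, public 6-row) linkage-attack demonstration tables."""
    private = _load_csv("linkage_private.csv", dtype=str)
    public = _load_csv("linkage_public.csv", dtype=str)
    return private, public


def reference_loss_grids() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The recorded (generalization, structure) loss grids, indexed by k
    with the weight a as float column labels."""
    out = []
    for name in ("generalization_losses.csv", "structure_losses.csv"):
        df = _load_csv(name).set_index("k")
        df.columns = [float(c) for c in df.columns]
        out.append(df)
    return out[0], out[1]


# --------------------------------------------------------------------- #
# synthetic edges
# --------------------------------------------------------------------- #


def synth_edges(
    n: int,
    mean_degree: float,
    model: str = "er",
    seed: int = 0,
    rewire_prob: float = 0.1,
) -> list[tuple[str, str]]:
    """Seeded random edge list over string node ids "1".."n".

    ``er``: each pair linked independently with probability
    mean_degree/(n-1).  ``ring``: ring lattice of nearest neighbours with
    seeded rewiring (``rewire_prob=0`` keeps the pure lattice).
    Connectedness is not guaranteed; the distance measures handle
    disconnected pairs.
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    if not 0 < mean_degree < n:
        raise ParameterError(
            f"mean_degree must lie in (0, n), got {mean_degree}"
        )
    if model == "er":
        p = mean_degree / (n - 1)
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif model == "ring":
        g = nx.watts_strogatz_graph(
            n, int(round(mean_degree)), rewire_prob, seed=seed
        )
    else:
        raise ParameterError(f"unknown edge model: {model!r}")
    return [(str(u + 1), str(v + 1)) for u, v in sorted(g.edges())]


# --------------------------------------------------------------------- #
# linkage attack
# --------------------------------------------------------------------- #


@dataclass(frozen=True)
class LinkageResult:
    """Outcome of joining a public table against a private one on QIDs."""

    matches: dict[str, tuple[str, ...]]  # public id -> matching private ids

    @property
    def summary(self) -> dict[str, int]:
        sizes = [len(v) for v in self.matches.values()]
        return {
            "unmatched": sum(s == 0 for s in sizes),
            "unique": sum(s == 1 for s in sizes),
            "ambiguous": sum(s >= 2 for s in sizes),
        }

    @property
    def unique_matches(self) -> dict[str, str]:
        return {p: m[0] for p, m in self.matches.items() if len(m) == 1}


def _check_qids(private: pd.DataFrame, public: pd.DataFrame,
                qids: Sequence[str]) -> None:
    for col in qids:
        for name, df in (("private", private), ("public", public)):
            if col not in df.columns:
                raise InputError(f"column {col!r} missing from {name} table")


def linkage_attack(
    private: pd.DataFrame, public: pd.DataFrame, qids: Sequence[str]
) -> LinkageResult:
    """Exact join on the quasi-identifiers: for each public record, the set
    of private records agreeing on every QID column."""
    qids = list(qids)
    _check_qids(private, public, qids)

    def key(df: pd.DataFrame, i: int) -> tuple:
        return tuple(str(df[c].iloc[i]).strip() for c in qids)

    priv_keys = [key(private, i) for i in range(len(private))]
    matches = {}
    for i in range(len(public)):
        pk = key(public, i)
        hit = tuple(
            str(private["ID"].iloc[j]).strip()
            for j, k in enumerate(priv_keys)
            if k == pk
        )
        matches[str(public["ID"].iloc[i]).strip()] = hit
    return LinkageResult(matches)


def linkage_schema(
    private: pd.DataFrame, public: pd.DataFrame
) -> AttributeSchema:
    """Default schema for the bundled linkage tables: Age numerical, zip
    under the 3-digit-prefix tree built from both tables' codes."""
    zips = set(private["Zip code"].astype(str)) | set(
        public["Zip code"].astype(str)
    )
    return AttributeSchema(
        numerical=["Age"],
        categorical={"Zip code": Hierarchy.prefix(sorted(zips))},
    )


def generalized_linkage(
    private: pd.DataFrame,
    public: pd.DataFrame,
    qids: Sequence[str],
    schema: AttributeSchema,
    levels: Mapping[str, float],
) -> LinkageResult:
    """Join after generalizing both tables identically.

    ``levels`` maps each categorical QID to a number of hierarchy levels to
    climb (0 = raw) and each numerical QID to a bin width (0 = raw,
    ``inf`` = suppress to a single bin).  Coarser levels can only enlarge
    match sets, provided numeric widths are nested (each a multiple of the
    previous).
    """
    qids = list(qids)
    _check_qids(private, public, qids)

    def generalize(col: str, raw: str) -> str:
        raw = str(raw).strip()
        level = levels.get(col, 0)
        if col in schema.categorical:
            return schema.categorical[col].ancestor(raw, int(level))
        if col in schema.numerical:
            w = float(level)
            if w == 0:
                return raw
            if math.isinf(w):
                return "*"
            lo = math.floor(float(raw) / w) * w
            return f"[{lo:g},{lo + w:g})"
        return raw

    def table_keys(df: pd.DataFrame) -> list[tuple]:
        return [
            tuple(generalize(c, df[c].iloc[i]) for c in qids)
            for i in range(len(df))
        ]

    priv_keys = table_keys(private)
    matches = {}
    for i, pk in enumerate(table_keys(public)):
        hit = tuple(
            str(private["ID"].iloc[j]).strip()
            for j, k in enumerate(priv_keys)
            if k == pk
        )
        matches[str(public["ID"].iloc[i]).strip()] = hit
    return LinkageResult(matches)


# --------------------------------------------------------------------- #
# (k, a) sweeps
# --------------------------------------------------------------------- #


@dataclass
class LossGrid:
    """Loss reports over a (k, a) parameter grid."""

    k_values: list[int]
    a_values: list[float]
    reports: list[list[LossReport]]  # [k index][a index]

    def report(self, k: int, a: float) -> LossReport:
        return self.reports[self.k_values.index(k)][self.a_values.index(a)]

    def to_frame(self) -> pd.DataFrame:
        rows = [r.csv_row() for row in self.reports for r in row]
        return pd.DataFrame(
            rows, columns=["k", "a", "gloss", "sloss", "total"]
        )

    def min_total(self) -> tuple[int, float, float]:
        """(k, a, total) of the grid cell with minimal combined loss."""
        best = min(
            (r for row in self.reports for r in row), key=lambda r: r.total
        )
        return best.k, best.a, best.total


def sweep_losses(
    g: SocialGraph,
    records: Mapping[str, NodeRecord],
    schema: AttributeSchema,
    k_grid: Iterable[int] = DEFAULT_K_GRID,
    a_grid: Iterable[float] = DEFAULT_A_GRID,
) -> LossGrid:
    """Run the greedy clustering and both losses on every (k, a) cell."""
    k_grid, a_grid = list(k_grid), list(a_grid)
    for k in k_grid:
        if k > g.n:
            raise ParameterError(f"grid value k={k} exceeds n={g.n}")
    ranges = global_ranges(records.values(), schema)
    reports = []
    for k in k_grid:
        row = []
        for a in a_grid:
            part = greedy_k_cluster(g, records, schema, ClusterParams(k, a))
            row.append(evaluate_losses(g, part, records, schema, ranges, k, a))
        reports.append(row)
    return LossGrid(k_grid, a_grid, reports)


# --------------------------------------------------------------------- #
# brute-force oracle
# --------------------------------------------------------------------- #


def _set_partitions(items: list[str]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield smaller + [[first]]


def brute_force_partition(
    g: SocialGraph,
    records: Mapping[str, NodeRecord],
    schema: AttributeSchema,
    k: int,
    a: float = 0.5,
) -> Partition:
    """Exhaustively optimal partition into clusters of size >= k.

    Minimizes total loss (GLoss + SLoss) over *all* legal partitions; ties
    break on the lexicographically smallest canonical encoding.  Refuses
    n > 10 (Bell-number growth).
    """
    ClusterParams(k, a)  # validate the parameter pair
    if g.n > 10:
        raise ParameterError(f"brute force is capped at n=10, got n={g.n}")
    if k > g.n:
        raise ParameterError(f"k={k} exceeds the node count n={g.n}")
    ranges = global_ranges(records.values(), schema)
    order = {v: i for i, v in enumerate(g.node_ids)}

    def canonical(blocks: list[list[str]]):
        return tuple(
            sorted(tuple(sorted(b, key=order.get)) for b in blocks)
        )

    best = None
    for blocks in _set_partitions(list(g.node_ids)):
        if any(len(b) < k for b in blocks):
            continue
        enc = canonical(blocks)
        part = Partition(enc)
        rep = evaluate_losses(g, part, records, schema, ranges, k, a)
        key = (rep.total, enc)
        if best is None or key < best[0]:
            best = (key, part)
    assert best is not None  # k <= n guarantees >= 1 legal partition
    return best[1]


# --------------------------------------------------------------------- #
# regression report against the reference grid cells
# --------------------------------------------------------------------- #

#: Printed cells the original study singles out: the best generalization
#: loss and the best structure loss over the sweep.
REFERENCE_BEST_GLOSS = {"k": 21, "a": 1.0, "value": 0.116333}
REFERENCE_BEST_SLOSS = {"k": 3, "a": [0.2, 0.4, 0.6, 0.8], "value": 0.150157}


def regression_report(
    g: SocialGraph | None = None,
    seed: int = 1,
    mean_degree: float = DEFAULT_MEAN_DEGREE,
) -> dict:
    """Recompute the singled-out grid cells and report deviations.

    The original network's edge list was never published; by default the
    seeded synthetic stand-in is used (pass ``g`` to evaluate a real edge
    list instead).  Each entry carries the recomputed value, the reference
    value, their deviation, and a cluster-level breakdown (sizes and
    intra-edge counts), so discrepancies can be traced.
    """
    if g is None:
        g = benchmark_network(seed, mean_degree)
    records = {r.id: r for r in benchmark_records()}
    schema = benchmark_schema()
    ranges = global_ranges(records.values(), schema)

    def run(k: int, a: float) -> tuple[LossReport, list[dict]]:
        part = greedy_k_cluster(g, records, schema, ClusterParams(k, a))
        rep = evaluate_losses(g, part, records, schema, ranges, k, a)
        breakdown = [
            {
                "size": len(c),
                "intra_edges": intra_edges(g, c),
                "intra_sl": rep.per_cluster_intra[i],
            }
            for i, c in enumerate(part.clusters)
        ]
        return rep, breakdown

    out: dict[str, dict] = {}
    rep, breakdown = run(REFERENCE_BEST_GLOSS["k"], REFERENCE_BEST_GLOSS["a"])
    out["gloss_k21_a1"] = {
        "value": rep.gloss,
        "reference": REFERENCE_BEST_GLOSS["value"],
        "deviation": rep.gloss - REFERENCE_BEST_GLOSS["value"],
        "clusters": breakdown,
    }
    for a in REFERENCE_BEST_SLOSS["a"]:
        rep, breakdown = run(REFERENCE_BEST_SLOSS["k"], a)
        out[f"sloss_k3_a{a:g}"] = {
            "value": rep.sloss,
            "reference": REFERENCE_BEST_SLOSS["value"],
            "deviation": rep.sloss - REFERENCE_BEST_SLOSS["value"],
            "clusters": breakdown,
        }
    return out


def reference_min_total_loss() -> tuple[int, float, float]:
    """(k, a, total) minimizing gloss+sloss over the reference grids."""
    gl, sl = reference_loss_grids()
    best = None
    for k in gl.index:
        for a in gl.columns:
            t = total_loss(float(gl.loc[k, a]), float(sl.loc[k, a]))
            if best is None or t < best[2]:
                best = (int(k), float(a), t)
    assert best is not None
    return best
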