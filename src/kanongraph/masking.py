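"""Masked-graph construction, serialization, and input readers.

The published form of an anonymized network is the masked graph ``G_m``:
one supernode ``SC_i`` per cluster carrying the cluster's generalized
attribute record, its member count ``|s_i|`` and its internal edge count
``|E_si|``, plus superedges carrying the inter-cluster edge counts
``|E_si,sj|``.  No raw node identifier survives into the published form,
and edge counts are conserved:

    sum_i |E_si| + sum_{i<j} |E_si,sj| = |E|.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .attributes import (
    AttributeSchema,
    GeneralizedRecord,
    Hierarchy,
    NodeRecord,
    generalize_cluster,
)
from .errors import InputError, ValidationError
from .graph import SocialGraph, from_edge_list
from .loss import Partition, inter_edges, intra_edges

_INTERVAL_RE = re.compile(r"^(.*[^.])\.\.([^.].*)$")

#: Tokens recognized as an (optional) edge-list header line.
_HEADER_TOKENS = {
    "source", "target", "from", "to", "u", "v",
    "id1", "id2", "node1", "node2",
}


@dataclass(frozen=True)
class Supernode:
    """Published cluster: generalized record, size, internal edge count."""

    label: str
    generalized: GeneralizedRecord
    size: int
    intra_edge_count: int


@dataclass(frozen=True)
class MaskedGraph:
    """The published network of supernodes and counted superedges."""

    supernodes: tuple[Supernode, ...]
    superedges: tuple[tuple[int, int, int], ...]  # (i, j, cross count), i < j
    numerical: tuple[str, ...]
    categorical: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.supernodes)

    @property
    def total_size(self) -> int:
        return sum(sn.size for sn in self.supernodes)

    @property
    def total_edges(self) -> int:
        return sum(sn.intra_edge_count for sn in self.supernodes) + sum(
            c for _, _, c in self.superedges
        )


def build_masked_graph(
    g: SocialGraph,
    partition: Partition,
    records: Mapping[str, NodeRecord],
    schema: AttributeSchema,
) -> MaskedGraph:
    """Collapse each cluster into a supernode; count edges within/between."""
    partition.validate_cover(g.node_ids)
    if set(records) != set(g.node_ids):
        raise ValidationError("records do not cover the graph's node set")
    cs = partition.clusters
    supernodes = tuple(
        Supernode(
            label=f"SC{i + 1}",
            generalized=generalize_cluster([records[v] for v in c], schema),
            size=len(c),
            intra_edge_count=intra_edges(g, c),
        )
        for i, c in enumerate(cs)
    )
    superedges = []
    for i in range(len(cs)):
        for j in range(i + 1, len(cs)):
            cross = inter_edges(g, cs[i], cs[j])
            if cross > 0:
                superedges.append((i, j, cross))
    masked = MaskedGraph(
        supernodes,
        tuple(superedges),
        tuple(schema.numerical),
        tuple(schema.categorical),
    )
    if masked.total_size != g.n or masked.total_edges != g.edge_count:
        raise ValidationError("masked graph violates conservation invariants")
    return masked


# --------------------------------------------------------------------- #
# serialization
# --------------------------------------------------------------------- #


def _masked_to_nx(m: MaskedGraph) -> nx.Graph:
    out = nx.Graph()
    out.graph["numerical"] = ",".join(m.numerical)
    out.graph["categorical"] = ",".join(m.categorical)
    for sn in m.supernodes:
        attrs: dict[str, object] = {
            "size": sn.size,
            "intra_edges": sn.intra_edge_count,
        }
        for a, (lo, hi) in sn.generalized.intervals.items():
            attrs[a] = f"{lo!r}..{hi!r}"
        for a, label in sn.generalized.categories.items():
            attrs[a] = label
        out.add_node(sn.label, **attrs)
    for i, j, c in m.superedges:
        out.add_edge(m.supernodes[i].label, m.supernodes[j].label,
                     cross_count=c)
    return out


def write_masked_graph(m: MaskedGraph, path, format: str = "graphml") -> None:
    """Write a masked graph as GraphML or JSON (round-trips losslessly)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_masked_to_nx(m), path)
    elif format == "json":
        doc = {
            "numerical": list(m.numerical),
            "categorical": list(m.categorical),
            "supernodes": [
                {
                    "label": sn.label,
                    "size": sn.size,
                    "intra_edges": sn.intra_edge_count,
                    "intervals": {
                        a: [lo, hi]
                        for a, (lo, hi) in sn.generalized.intervals.items()
                    },
                    "categories": dict(sn.generalized.categories),
                }
                for sn in m.supernodes
            ],
            "superedges": [list(e) for e in m.superedges],
        }
        path.write_text(json.dumps(doc, indent=2))
    else:
        raise InputError(f"unknown masked-graph format: {format!r}")


def read_masked_graph(path, format: str = "graphml") -> MaskedGraph:
    """Read back a masked graph written by :func:`write_masked_graph`."""
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text())
        supernodes = tuple(
            Supernode(
                label=sn["label"],
                generalized=GeneralizedRecord(
                    {a: (float(lo), float(hi))
                     for a, (lo, hi) in sn["intervals"].items()},
                    {a: str(v) for a, v in sn["categories"].items()},
                ),
                size=int(sn["size"]),
                intra_edge_count=int(sn["intra_edges"]),
            )
            for sn in doc["supernodes"]
        )
        superedges = tuple(tuple(int(x) for x in e) for e in doc["superedges"])
        return MaskedGraph(
            supernodes,
            superedges,  # type: ignore[arg-type]
            tuple(doc["numerical"]),
            tuple(doc["categorical"]),
        )
    if format != "graphml":
        raise InputError(f"unknown masked-graph format: {format!r}")
    g = nx.read_graphml(path)
    numerical = tuple(x for x in g.graph.get("numerical", "").split(",") if x)
    categorical = tuple(
        x for x in g.graph.get("categorical", "").split(",") if x
    )
    labels = sorted(g.nodes, key=lambda l: int(str(l)[2:]))
    index = {label: i for i, label in enumerate(labels)}
    supernodes = []
    for label in labels:
        data = g.nodes[label]
        intervals = {}
        for a in numerical:
            match = _INTERVAL_RE.match(str(data[a]))
            if not match:
                raise InputError(f"malformed interval for {a!r}: {data[a]!r}")
            intervals[a] = (float(match.group(1)), float(match.group(2)))
        categories = {a: str(data[a]) for a in categorical}
        supernodes.append(
            Supernode(
                label=str(label),
                generalized=GeneralizedRecord(intervals, categories),
                size=int(data["size"]),
                intra_edge_count=int(data["intra_edges"]),
            )
        )
    superedges = sorted(
        (min(index[u], index[v]), max(index[u], index[v]),
         int(d["cross_count"]))
        for u, v, d in g.edges(data=True)
    )
    return MaskedGraph(
        tuple(supernodes), tuple(superedges), numerical, categorical
    )


# --------------------------------------------------------------------- #
# input readers
# --------------------------------------------------------------------- #


def read_edge_list(path, node_ids) -> SocialGraph:
    """Two-column tab- or comma-separated edge file, optional header."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    edges = []
    for lineno, ln in enumerate(lines):
        sep = "\t" if "\t" in ln else ","
        parts = [p.strip() for p in ln.split(sep)]
        if len(parts) != 2:
            raise InputError(
                f"{path}: line {lineno + 1}: expected two columns, "
                f"got {len(parts)}"
            )
        if lineno == 0 and all(p.lower() in _HEADER_TOKENS for p in parts):
            continue
        edges.append((parts[0], parts[1]))
    return from_edge_list(edges, node_ids)


def read_schema(schema_path, hierarchy_path) -> AttributeSchema:
    """Schema JSON: ``{"numerical": [...], "categorical": {attr: hname}}``;
    hierarchy JSON: ``{hname: {root: {child: {...}}}}``."""
    try:
        schema_doc = json.loads(Path(schema_path).read_text())
        hier_doc = json.loads(Path(hierarchy_path).read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"malformed JSON: {exc}") from exc
    numerical = [str(a) for a in schema_doc.get("numerical", [])]
    categorical = {}
    for attr, hname in schema_doc.get("categorical", {}).items():
        if hname not in hier_doc:
            raise InputError(
                f"categorical attribute {attr!r} names unknown hierarchy "
                f"{hname!r}"
            )
        categorical[str(attr)] = Hierarchy(hier_doc[hname])
    return AttributeSchema(numerical, categorical)


def read_node_table(path, schema: AttributeSchema):
    """CSV ``id,<attr>,...``; extra columns ride along as sensitive values.

    Returns an ordered ``{id: NodeRecord}`` dict (CSV row order).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if df.columns[0].lower() != "id":
        raise InputError(f"{path}: first column must be 'id'")
    df = df.rename(columns={df.columns[0]: "id"})
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise InputError(f"{path}: duplicate id {dup!r}")
    declared = list(schema.numerical) + list(schema.categorical)
    for attr in declared:
        if attr not in df.columns:
            raise InputError(f"{path}: missing column {attr!r}")
    extra = [c for c in df.columns if c != "id" and c not in declared]
    records: dict[str, NodeRecord] = {}
    for row_pos, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        values: dict[str, object] = {}
        for attr in schema.numerical:
            raw = str(row_d[attr]).strip()
            try:
                values[attr] = float(raw)
            except ValueError:
                raise InputError(
                    f"{path}: row {row_pos}, column {attr!r}: "
                    f"cannot parse {raw!r} as a number"
                ) from None
        for attr in schema.categorical:
            values[attr] = str(row_d[attr]).strip()
        rec = NodeRecord(
            id=str(row_d["id"]).strip(),
            values=values,
            sensitive={c: row_d[c] for c in extra},
        )
        rec.validate(schema)
        records[rec.id] = rec
    return records


def read_inputs(nodes_csv, edges_file, schema_json, hierarchy_json):
    """Load and cross-validate the full input bundle.

    Returns ``(SocialGraph, {id: NodeRecord}, AttributeSchema)``; node order
    is the CSV row order.
    """
    schema = read_schema(schema_json, hierarchy_json)
    records = read_node_table(nodes_csv, schema)
    g = read_edge_list(edges_file, list(records))
    return g, records, schema
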