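from __future__ import annotations

import numpy as np
import pytest

import kanongraph as kg

#: Raw nested-dict tree shared with the naive oracle (kept as plain data so
#: both implementations parse it independently).
CODE_TREE = {"*": {"A": {"A1": {}, "A2": {}}, "B": {"B1": {}, "B2": {}}}}
GENDER_TREE = {"*": {"M": {}, "F": {}}}


def random_instance(seed: int, n: int = 8, p: float = 0.3):
    """Seeded random attributed graph: adjacency, records, schema, trees."""
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    ids = [str(i + 1) for i in range(n)]
    g = kg.SocialGraph(ids, adj)
    ages = [float(rng.integers(20, 81)) for _ in range(n)]
    genders = [str(rng.choice(["M", "F"])) for _ in range(n)]
    codes = [str(rng.choice(["A1", "A2", "B1", "B2"])) for _ in range(n)]
    records = {
        ids[i]: kg.NodeRecord(
            ids[i],
            {"Age": ages[i], "Gender": genders[i], "Code": codes[i]},
        )
        for i in range(n)
    }
    schema = kg.AttributeSchema(
        ["Age"],
        {"Gender": kg.Hierarchy(GENDER_TREE), "Code": kg.Hierarchy(CODE_TREE)},
    )
    trees = {"Gender": GENDER_TREE, "Code": CODE_TREE}
    return g, records, schema, ages, {"Gender": genders, "Code": codes}, trees


def random_partition(rng: np.random.Generator, ids: list[str], min_size=1):
    """Seeded random partition of ``ids`` with blocks of >= min_size."""
    ids = list(ids)
    rng.shuffle(ids)
    clusters, i = [], 0
    while i < len(ids):
        size = int(rng.integers(min_size, min(len(ids) - i, 4) + 1))
        if len(ids) - (i + size) < min_size and i + size < len(ids):
            size = len(ids) - i
        clusters.append(ids[i:i + size])
        i += size
    return kg.Partition(clusters)


@pytest.fixture(scope="session")
def benchmark():
    """The 60-patient benchmark bundle with its seeded synthetic network."""
    records = {r.id: r for r in kg.benchmark_records()}
    schema = kg.benchmark_schema()
    g = kg.benchmark_network(seed=1)
    ranges = kg.global_ranges(records.values(), schema)
    return g, records, schema, ranges


@pytest.fixture(scope="session")
def benchmark_sweep(benchmark):
    """Full default-grid sweep on the benchmark (shared: it takes seconds)."""
    g, records, schema, _ = benchmark
    return g, records, schema, kg.sweep_losses(g, records, schema)


@pytest.fixture()
def path4():
    """Path graph A-B-C-D."""
    return kg.from_edge_list(
        [("A", "B"), ("B", "C"), ("C", "D")], ["A", "B", "C", "D"]
    )
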