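"""Bundled datasets, synthetic edges, linkage auditing, sweeps, oracle."""

import itertools

import numpy as np
import pytest

import kanongraph as kg
from conftest import random_instance


class TestBenchmarkTable:
    def test_record_count(self):
        assert len(kg.benchmark_records()) == 60

    def test_spot_check_record_5(self):
        r = {r.id: r for r in kg.benchmark_records()}["5"]
        assert r.category("Gender") == "M"
        assert r.numeric("Age") == 56.0
        assert r.category("Zip code") == "32211"
        assert r.category("Marriage") == "Marriage"
        assert r.category("Smoke") == "N"
        assert r.sensitive["Diagnosis"] == "AA"

    def test_age_extremes(self):
        ages = [r.numeric("Age") for r in kg.benchmark_records()]
        assert min(ages) == 19.0 and max(ages) == 84.0

    def test_schema_shape(self):
        schema = kg.benchmark_schema()
        assert schema.numerical == ["Age"]
        assert list(schema.categorical) == [
            "Gender", "Marriage", "Smoke", "Zip code"
        ]
        assert schema.categorical["Zip code"].height == 2

    def test_all_records_conform(self):
        schema = kg.benchmark_schema()
        for r in kg.benchmark_records():
            r.validate(schema)


class TestLinkAttackTables:
    def test_shapes(self):
        private, public = kg.link_attack_tables()
        assert len(private) == 7 and len(public) == 6

    def test_spot_cells(self):
        private, public = kg.link_attack_tables()
        row5 = private.iloc[4]
        assert (row5["Zip code"], row5["Age"], row5["Disease"]) == (
            "273207", "50", "cancer"
        )
        row4 = public.iloc[3]
        assert (row4["Name"], row4["Gender"], row4["Zip code"],
                row4["Age"]) == ("Sam", "Female", "273207", "50")


class TestPrintedGrids:
    def test_dimensions(self):
        gl, sl = kg.reference_loss_grids()
        assert gl.shape == (10, 6) and sl.shape == (10, 6)
        assert list(gl.index) == [3, 6, 9, 12, 15, 18, 21, 24, 27, 30]
        assert list(gl.columns) == [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]

    def test_spot_cells(self):
        gl, sl = kg.reference_loss_grids()
        assert gl.loc[21, 1.0] == pytest.approx(0.116333)
        assert sl.loc[3, 0.4] == pytest.approx(0.150157)


class TestSynthEdges:
    def test_pure_ring_is_cycle(self):
        edges = kg.synth_edges(4, 2, model="ring", seed=0, rewire_prob=0.0)
        assert sorted(edges) == [
            ("1", "2"), ("1", "4"), ("2", "3"), ("3", "4")
        ]

    def test_determinism(self):
        a = kg.synth_edges(60, 4, "er", seed=7)
        b = kg.synth_edges(60, 4, "er", seed=7)
        assert a == b

    def test_er_edge_count_near_expectation(self):
        """|E| ~ Binomial(C(n,2), d/(n-1)); check within 4 sigma."""
        n, d = 60, 4.0
        edges = kg.synth_edges(n, d, "er", seed=1)
        mean = n * d / 2
        p = d / (n - 1)
        sigma = (n * (n - 1) / 2 * p * (1 - p)) ** 0.5
        assert abs(len(edges) - mean) < 4 * sigma

    @pytest.mark.parametrize("n,d,model", [
        (1, 1, "er"), (10, 0, "er"), (10, 12, "er"), (10, 4, "nope"),
    ])
    def test_invalid_parameters(self, n, d, model):
        with pytest.raises(kg.ParameterError):
            kg.synth_edges(n, d, model, seed=0)


class TestLinkageAttack:
    @pytest.fixture(autouse=True)
    def _tables(self):
        self.private, self.public = kg.link_attack_tables()
        self.qids = ["Zip code", "Age"]

    def test_sam_uniquely_reidentified_as_cancer(self):
        res = kg.linkage_attack(self.private, self.public, self.qids)
        sam_id = self.public[self.public["Name"] == "Sam"]["ID"].iloc[0]
        (match,) = res.matches[sam_id]
        disease = self.private[self.private["ID"] == match]["Disease"].iloc[0]
        assert disease == "cancer"

    def test_mary_has_no_match(self):
        res = kg.linkage_attack(self.private, self.public, self.qids)
        mary_id = self.public[self.public["Name"] == "Mary"]["ID"].iloc[0]
        assert res.matches[mary_id] == ()

    def test_five_of_six_unique(self):
        res = kg.linkage_attack(self.private, self.public, self.qids)
        assert res.summary == {"unmatched": 1, "unique": 5, "ambiguous": 0}
        assert sum(res.summary.values()) == len(self.public)

    def test_missing_column_rejected(self):
        with pytest.raises(kg.InputError):
            kg.linkage_attack(self.private, self.public, ["Nope"])

    def test_zero_generalization_matches_raw_join(self):
        schema = kg.linkage_schema(self.private, self.public)
        raw = kg.linkage_attack(self.private, self.public, self.qids)
        gen = kg.generalized_linkage(
            self.private, self.public, self.qids, schema,
            {"Zip code": 0, "Age": 0},
        )
        assert gen.matches == raw.matches

    def test_full_generalization_matches_everything(self):
        schema = kg.linkage_schema(self.private, self.public)
        gen = kg.generalized_linkage(
            self.private, self.public, self.qids, schema,
            {"Zip code": 2, "Age": float("inf")},
        )
        assert all(
            len(m) == len(self.private) for m in gen.matches.values()
        )

    def test_monotone_in_generalization_level(self):
        """Match sets never shrink as either QID coarsens (nested levels)."""
        schema = kg.linkage_schema(self.private, self.public)
        zip_levels = [0, 1, 2]
        age_widths = [0, 10, float("inf")]
        sizes = {}
        for zl, aw in itertools.product(zip_levels, age_widths):
            res = kg.generalized_linkage(
                self.private, self.public, self.qids, schema,
                {"Zip code": zl, "Age": aw},
            )
            sizes[(zl, aw)] = {p: len(m) for p, m in res.matches.items()}
        for (zl, aw), per_record in sizes.items():
            for (zl2, aw2), per_record2 in sizes.items():
                if zl2 >= zl and age_widths.index(aw2) >= age_widths.index(aw):
                    assert all(
                        per_record2[p] >= per_record[p] for p in per_record
                    )


class TestSweep:
    def test_default_grid_on_benchmark(self, benchmark_sweep):
        g, _, _, grid = benchmark_sweep
        assert len(grid.k_values) == 10 and len(grid.a_values) == 6
        for row, k in zip(grid.reports, grid.k_values):
            for rep in row:
                assert 0.0 <= rep.gloss <= 1.0
                assert 0.0 <= rep.sloss <= 1.0

    def test_sweep_partitions_k_anonymous_and_conserving(self, benchmark_sweep):
        g, records, schema, grid = benchmark_sweep
        for k in grid.k_values:
            for a in grid.a_values:
                part = kg.greedy_k_cluster(
                    g, records, schema, kg.ClusterParams(k, a)
                )
                assert kg.assert_k_anonymous(part, k)
                m = kg.build_masked_graph(g, part, records, schema)
                assert m.total_edges == g.edge_count

    def test_grid_value_above_n_rejected(self, benchmark):
        g, records, schema, _ = benchmark
        with pytest.raises(kg.ParameterError):
            kg.sweep_losses(g, records, schema, k_grid=[61], a_grid=[0.5])

    def test_csv_shape(self, benchmark_sweep):
        *_, grid = benchmark_sweep
        df = grid.to_frame()
        assert list(df.columns) == ["k", "a", "gloss", "sloss", "total"]
        assert len(df) == 60


class TestBruteForce:
    def test_identical_pairs_found(self):
        """Edgeless graph with two identical attribute pairs: the zero-loss
        pairing is achievable and found."""
        g = kg.SocialGraph(["1", "2", "3", "4"], np.zeros((4, 4), dtype=int))
        schema = kg.AttributeSchema(
            ["Age"], {"Gender": kg.Hierarchy.flat(["M", "F"])}
        )
        records = {
            "1": kg.NodeRecord("1", {"Age": 30.0, "Gender": "M"}),
            "2": kg.NodeRecord("2", {"Age": 70.0, "Gender": "F"}),
            "3": kg.NodeRecord("3", {"Age": 30.0, "Gender": "M"}),
            "4": kg.NodeRecord("4", {"Age": 70.0, "Gender": "F"}),
        }
        part = kg.brute_force_partition(g, records, schema, 2)
        assert sorted(tuple(sorted(c)) for c in part.clusters) == [
            ("1", "3"), ("2", "4")
        ]

    def test_k_equals_n_single_cluster(self):
        g, records, schema, *_ = random_instance(0, n=4)
        part = kg.brute_force_partition(g, records, schema, 4)
        assert part.m == 1

    def test_refuses_large_n(self):
        g, records, schema, *_ = random_instance(0, n=11)
        with pytest.raises(kg.ParameterError):
            kg.brute_force_partition(g, records, schema, 2)


class TestRegressionReport:
    def test_report_structure(self):
        report = kg.regression_report(seed=1)
        assert set(report) == {
            "gloss_k21_a1", "sloss_k3_a0.2", "sloss_k3_a0.4",
            "sloss_k3_a0.6", "sloss_k3_a0.8",
        }
        for entry in report.values():
            assert 0.0 <= entry["value"] <= 1.0
            assert entry["deviation"] == pytest.approx(
                entry["value"] - entry["reference"]
            )
            assert all(c["size"] >= 1 for c in entry["clusters"])
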