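"""Mean-threshold retention and bipartite network construction/export."""

import math

import numpy as np
import pytest

from pp2anet.config_io import (
    CoexpressionRecord,
    CoexpressionTable,
    StressSet,
    SubunitConfig,
    ValidationError,
)
from pp2anet.network import (
    SUNode,
    apply_threshold,
    build_bipartite_network,
    compute_threshold,
    export_gexf,
    load_gexf,
)
from pp2anet.synthetic_data import SyntheticSpec, generate_coexpression


def rec(gene, score, member="A_1", stress="Cold", subunit="A"):
    return CoexpressionRecord(gene, subunit, member, stress, score)


class TestComputeThreshold:
    def test_constant_scores_all_retained_at_inclusive_mean(self):
        table = CoexpressionTable([rec(f"g{i}", 0.3) for i in range(4)])
        report = compute_threshold(table, "A")
        assert report.mean_score == pytest.approx(0.3)
        assert report.n_after == report.n_before == 4

    def test_forced_arithmetic_fixture(self):
        table = CoexpressionTable(
            [rec(f"g{i}", s) for i, s in enumerate([0.1, 0.2, 0.3, 0.4])]
        )
        report = compute_threshold(table, "A")
        assert report.mean_score == pytest.approx(0.25)
        assert report.n_after == 2

    def test_pooled_mean_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(-1, 1, size=10_000)
        table = CoexpressionTable([rec(f"g{i}", float(s)) for i, s in enumerate(scores)])
        report = compute_threshold(table, "A")
        oracle = math.fsum(scores) / len(scores)
        assert abs(report.mean_score - oracle) < 1e-12

    def test_per_stress_mode_uses_stress_specific_means(self):
        table = CoexpressionTable(
            [rec("g1", 0.0, stress="Cold"), rec("g2", 0.2, stress="Cold"),
             rec("g3", 0.8, stress="Heat"), rec("g4", 1.0, stress="Heat")]
        )
        report = compute_threshold(table, "A", mode="per_stress")
        assert report.per_stress_means == pytest.approx({"Cold": 0.1, "Heat": 0.9})
        assert report.n_after == 2  # one survivor per stress

    def test_missing_subunit_rejected(self):
        with pytest.raises(ValidationError, match="no records"):
            compute_threshold(CoexpressionTable([]), "A")


class TestApplyThreshold:
    def test_idempotent_on_constant_table(self):
        table = CoexpressionTable([rec(f"g{i}", 0.5) for i in range(3)])
        out = apply_threshold(table, compute_threshold(table, "A"))
        assert out.records == table.records

    def test_forced_fixture_keeps_top_half(self):
        table = CoexpressionTable(
            [rec(f"g{i}", s) for i, s in enumerate([0.1, 0.2, 0.3, 0.4])]
        )
        out = apply_threshold(table, compute_threshold(table, "A"))
        assert [r.score for r in out] == [0.3, 0.4]

    def test_random_table_matches_per_record_oracle_and_preserves_order(self):
        rng = np.random.default_rng(1)
        table = CoexpressionTable(
            [rec(f"g{i}", float(s)) for i, s in enumerate(rng.uniform(-1, 1, 2000))]
        )
        report = compute_threshold(table, "A")
        out = apply_threshold(table, report)
        oracle = [r for r in table if r.score >= report.mean_score]
        assert out.records == oracle

    def test_absolute_mode_retains_strong_negative_correlations(self):
        table = CoexpressionTable([rec("g1", -0.9), rec("g2", 0.1), rec("g3", 0.2)])
        report = compute_threshold(table, "A", absolute=True)
        out = apply_threshold(table, report)
        assert {r.gene_id for r in out} == {"g1"}


@pytest.fixture
def tiny_config():
    return SubunitConfig({"A": ("A_1", "A_2")}), StressSet(("Cold", "Heat"))


class TestBuildNetwork:
    def test_empty_input_gives_empty_network(self, stresses, subunits):
        net = build_bipartite_network(CoexpressionTable([]), "A", stresses, subunits)
        assert net.n_nodes == 0 and net.edges == []

    def test_hand_enumerated_fixture(self, tiny_config):
        config, stresses = tiny_config
        table = CoexpressionTable(
            [
                rec("g1", 0.5, member="A_1", stress="Cold"),
                rec("g1", 0.6, member="A_2", stress="Heat"),
                rec("g2", 0.7, member="A_1", stress="Cold"),
            ]
        )
        net = build_bipartite_network(table, "A", stresses, config)
        assert net.gene_nodes == {"g1", "g2"}
        assert net.su_nodes == {SUNode("Cold", "A_1"), SUNode("Heat", "A_2")}
        assert len(net.edges) == 3

    def test_full_coverage_gives_all_stress_member_su_nodes(
        self, stresses, subunits
    ):
        # a planted hub guarantees an above-mean record in every pair
        spec = SyntheticSpec(n_genes=10, coverage=1.0, planted_hubs=("H1",), seed=2)
        table, _ = generate_coexpression(spec)
        for subunit, expected in (("A", 35), ("B", 70), ("C", 14)):
            filtered = apply_threshold(table, compute_threshold(table, subunit))
            net = build_bipartite_network(filtered, subunit, stresses, subunits)
            assert len(net.su_nodes) == expected

    def test_every_node_has_degree_at_least_one_and_edges_equal_records(
        self, stresses, subunits, small_table
    ):
        table, _ = small_table
        filtered = apply_threshold(table, compute_threshold(table, "B"))
        net = build_bipartite_network(filtered, "B", stresses, subunits)
        adj = net.adjacency()
        assert all(neigh for neigh in adj.values())
        assert len(net.edges) == len(filtered)
        # bipartiteness: edges always join a gene to an SU node
        for gene, su, _ in net.edges:
            assert gene in net.gene_nodes and su in net.su_nodes

    def test_raising_threshold_never_grows_the_network(
        self, stresses, subunits, small_table
    ):
        table, _ = small_table
        report = compute_threshold(table, "A")
        base = build_bipartite_network(
            apply_threshold(table, report), "A", stresses, subunits
        )
        report.mean_score += 0.1
        higher = build_bipartite_network(
            apply_threshold(table, report), "A", stresses, subunits
        )
        assert higher.n_nodes <= base.n_nodes
        assert len(higher.edges) <= len(base.edges)

    def test_foreign_subunit_record_rejected(self, stresses, subunits):
        table = CoexpressionTable([rec("g1", 0.5, subunit="B", member="B_1")])
        with pytest.raises(ValidationError):
            build_bipartite_network(table, "A", stresses, subunits)


class TestGexfExport:
    def test_round_trip_preserves_counts_and_weights(
        self, tmp_path, stresses, subunits, small_table
    ):
        table, _ = small_table
        filtered = apply_threshold(table, compute_threshold(table, "A"))
        net = build_bipartite_network(filtered, "A", stresses, subunits)
        path = tmp_path / "net.gexf"
        export_gexf(net, path)
        again = load_gexf(path, subunit="A")
        assert again.gene_nodes == net.gene_nodes
        assert again.su_nodes == net.su_nodes
        original = {(g, su): round(w, 6) for g, su, w in net.edges}
        reloaded = {(g, su): round(w, 6) for g, su, w in again.edges}
        assert reloaded == original

    def test_weight_rounds_to_six_decimals(self, tmp_path, tiny_config):
        config, stresses = tiny_config
        table = CoexpressionTable([rec("g1", 0.123456789)])
        net = build_bipartite_network(table, "A", stresses, config)
        path = tmp_path / "w.gexf"
        export_gexf(net, path)
        again = load_gexf(path)
        assert again.edges[0][2] == pytest.approx(0.123457, abs=1e-9)

    def test_empty_network_exports_valid_gexf(self, tmp_path, stresses, subunits):
        net = build_bipartite_network(CoexpressionTable([]), "A", stresses, subunits)
        path = tmp_path / "empty.gexf"
        export_gexf(net, path)
        again = load_gexf(path)
        assert again.n_nodes == 0 and again.edges == []
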