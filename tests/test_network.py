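import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coexnet as cx
from coexnet.coexdb import CoexpressionDatabase


def toy_db(K, lists):
    return CoexpressionDatabase(
        K=K, partner_lists={g: tuple(ps) for g, ps in lists.items()}
    )


class TestBuildNetwork:
    def test_considered_pairs_paper_scale_formula(self, small_db, small_world):
        hits = list(small_world.genes[:250])
        net = cx.build_network(hits, small_db)
        assert net.considered_pairs == 250 * 41 * 41 == 420250

    @given(n_hits=st.integers(1, 30), k=st.integers(1, 20), n_absent=st.integers(0, 5))
    @settings(max_examples=40, deadline=None)
    def test_considered_pairs_counts_only_db_hits(self, n_hits, k, n_absent):
        genes = [f"g{i}" for i in range(n_hits + k + 1)]
        lists = {
            g: tuple((p, 1) for p in genes if p != g)[:k] for g in genes[:n_hits]
        }
        db = toy_db(k, lists)
        hits = genes[:n_hits] + [f"absent{i}" for i in range(n_absent)]
        net = cx.build_network(hits, db)
        assert net.considered_pairs == n_hits * (k + 1) ** 2

    def test_mutual_pair_sums_both_neighborhoods(self):
        db = toy_db(2, {"a": (("b", 2), ("x", 1)), "b": (("a", 3), ("y", 1))})
        net = cx.build_network(["a", "b"], db)
        # hand enumeration: a's 3x3 slots materialize (a,b) with weight 1*2,
        # b's slots add 1*3; x and y are not hits, so no other edge exists
        assert net.graph.number_of_edges() == 1
        assert net.graph["a"]["b"]["weight"] == 5
        assert net.considered_pairs == 2 * 9

    def test_partner_partner_pair_uses_multiplicity_product(self):
        db = toy_db(2, {"c": (("a", 2), ("b", 3))})
        net = cx.build_network(["a", "b", "c"], db)
        assert net.graph["a"]["b"]["weight"] == 6
        assert net.graph["c"]["a"]["weight"] == 2
        assert net.graph["c"]["b"]["weight"] == 3

    def test_disjoint_neighborhoods_yield_isolated_hits(self):
        db = toy_db(2, {"a": (("x", 1), ("y", 1)), "b": (("u", 1), ("v", 1))})
        net = cx.build_network(["a", "b"], db)
        assert net.graph.number_of_edges() == 0
        assert cx.hit_inclusion_fraction(net) == 0.0

    def test_db_absent_hits_become_flagged_isolated_nodes(self):
        db = toy_db(2, {"a": (("b", 1),)})
        net = cx.build_network(["a", "b", "ghost"], db)
        assert net.graph.nodes["ghost"]["db_absent"]
        assert net.graph.degree("ghost") == 0

    def test_hit_order_invariance(self, small_db, small_world):
        hits = list(small_world.members("up_shared"))
        a = cx.build_network(hits, small_db)
        b = cx.build_network(hits[::-1], small_db)
        assert {frozenset(e) for e in a.graph.edges} == {frozenset(e) for e in b.graph.edges}
        assert all(
            a.graph[u][v]["weight"] == b.graph[u][v]["weight"] for u, v in a.graph.edges
        )
        assert a.considered_pairs == b.considered_pairs

    def test_incident_weight_sum_is_twice_edge_sum(self, small_db, small_world):
        net = cx.build_network(list(small_world.members("up_shared")), small_db)
        incident = sum(
            sum(d["weight"] for _, _, d in net.graph.edges(n, data=True))
            for n in net.graph.nodes
        )
        assert incident == 2 * net.total_edge_weight()


class TestConnectivityMetrics:
    def test_complete_graph_inclusion_100(self):
        genes = ["a", "b", "c"]
        db = toy_db(2, {g: tuple((p, 1) for p in genes if p != g) for g in genes})
        net = cx.build_network(genes, db)
        assert cx.hit_inclusion_fraction(net) == 100.0

    def test_one_isolated_of_three(self):
        db = toy_db(1, {"a": (("b", 1),), "b": (("a", 1),), "c": (("x", 1),)})
        net = cx.build_network(["a", "b", "c"], db)
        assert cx.hit_inclusion_fraction(net) == pytest.approx(200 / 3)

    def test_connections_per_hit_single_weighted_edge(self):
        db = toy_db(1, {"a": (("b", 2),), "b": (("a", 2),)})
        net = cx.build_network(["a", "b"], db)
        # one edge of weight 4 touches both hits: (4 + 4) / 2
        assert cx.connections_per_hit(net) == pytest.approx(4.0)

    def test_connections_per_hit_unit_triangle(self):
        genes = ["a", "b", "c"]
        db = toy_db(2, {"a": (("b", 1),), "b": (("c", 1),), "c": (("a", 1),)})
        net = cx.build_network(genes, db)
        assert cx.connections_per_hit(net) == pytest.approx(2.0)

    def test_edgeless_network_zero(self):
        db = toy_db(1, {"a": (("x", 1),)})
        net = cx.build_network(["a"], db)
        assert cx.connections_per_hit(net) == 0.0

    def test_planted_module_far_exceeds_random_lists(self, small_world, small_db):
        """A planted module's network is saturated while random same-size
        lists carry an order of magnitude less connection weight.  (At a
        2000-gene universe a 60-gene random list still collides often, so the
        sharp contrast lives in the summed connection counts; inclusion
        separates fully only at genome scale.)"""
        planted = cx.build_network(list(small_world.members("up_shared")), small_db)
        rand_nets = [
            cx.build_network(genes, small_db)
            for genes in cx.random_gene_lists(small_world.genes, 60, n_lists=5, seed=5)
        ]
        assert cx.hit_inclusion_fraction(planted) > 95.0
        assert cx.hit_inclusion_fraction(planted) > max(
            cx.hit_inclusion_fraction(r) for r in rand_nets
        )
        assert cx.connections_per_hit(planted) > 10 * max(
            cx.connections_per_hit(r) for r in rand_nets
        )


class TestPredictGenes:
    def test_count_ordering_and_tiebreak(self):
        db = toy_db(
            3,
            {
                "h1": (("x", 1), ("y", 1), ("z", 1)),
                "h2": (("x", 1), ("y", 2)),
                "h3": (("x", 1),),
            },
        )
        # counts: x=3, y=3, z=1 -> (x, y) by lexicographic tie-break
        predicted, shortfall = cx.predict_genes(["h1", "h2", "h3"], db, 2)
        assert predicted == ["x", "y"]
        assert not shortfall

    def test_shortfall_flagged(self):
        db = toy_db(1, {"h": (("x", 1),)})
        predicted, shortfall = cx.predict_genes(["h"], db, 5)
        assert predicted == ["x"] and shortfall

    def test_no_connected_non_hits(self):
        db = toy_db(1, {"a": (("b", 1),), "b": (("a", 1),)})
        predicted, shortfall = cx.predict_genes(["a", "b"], db, 3)
        assert predicted == [] and shortfall

    def test_integrated_predicted_nodes_touch_hits(self, small_world, small_db):
        hits = list(small_world.members("up_private"))
        net = cx.build_network(hits, small_db)
        predicted, _ = cx.predict_genes(hits, small_db, 10)
        cx.integrate_predicted(net, predicted, hits, small_db)
        hit_set = set(hits)
        for p in net.predicted_nodes():
            assert any(nb in hit_set for nb in net.graph.neighbors(p))


class TestClusters:
    def two_clique_db(self):
        c1, c2 = ["a", "b", "c"], ["x", "y", "z"]
        lists = {g: tuple((p, 1) for p in c1 if p != g) for g in c1}
        lists |= {g: tuple((p, 1) for p in c2 if p != g) for g in c2}
        return toy_db(2, lists), c1 + c2

    def test_two_disjoint_cliques_two_clusters(self):
        db, genes = self.two_clique_db()
        net = cx.build_network(genes, db)
        clusters = cx.assign_clusters(net, min_size=3)
        assert clusters.numbered_labels() == ["1", "2"]
        assert clusters.members("1") == {"a", "b", "c"}  # tie broken by smallest member
        assert clusters.members("2") == {"x", "y", "z"}

    def test_isolated_node_labeled_zero_and_absent_dash(self):
        db = toy_db(1, {"a": (("b", 1),), "b": (("a", 1),), "c": (("q", 1),)})
        net = cx.build_network(["a", "b", "c", "ghost"], db)
        clusters = cx.assign_clusters(net, min_size=2)
        assert clusters.labels["c"] == "0"
        assert clusters.labels["ghost"] == "-"

    def test_override_applies(self):
        db, genes = self.two_clique_db()
        net = cx.build_network(genes, db)
        clusters = cx.assign_clusters(net, min_size=3, override={"a": "7"})
        assert clusters.labels["a"] == "7"


class TestExport:
    def test_triangle_export_and_roundtrip(self, tmp_path):
        db = toy_db(2, {"a": (("b", 1),), "b": (("c", 2),), "c": (("a", 3),)})
        net = cx.build_network(["a", "b", "c"], db)
        clusters = cx.assign_clusters(net, min_size=3)
        prefix = tmp_path / "net"
        paths = cx.export_network(net, clusters, prefix, node_means={"a": 1.0, "b": -2.0, "c": 0.0})
        sif_lines = paths["sif"].read_text().strip().splitlines()
        assert len(sif_lines) == 3
        assert all(line.split("\t")[1] == "coex" for line in sif_lines)
        edges = cx.read_exported_edges(prefix)
        assert edges == {("a", "b"): 1, ("b", "c"): 2, ("a", "c"): 3}
        nodes = paths["nodes"].read_text().strip().splitlines()
        assert len(nodes) == 1 + 3

    def test_empty_network_valid_files(self, tmp_path):
        db = toy_db(1, {"a": (("x", 1),)})
        net = cx.build_network(["a"], db)
        clusters = cx.assign_clusters(net, min_size=2)
        paths = cx.export_network(net, clusters, tmp_path / "empty")
        assert paths["sif"].read_text() == ""
        assert cx.read_exported_edges(tmp_path / "empty") == {}
        header = paths["edges"].read_text().splitlines()[0]
        assert header == "geneA\tgeneB\tweight"
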