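import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coexnet as cx
from conftest import toy_ranking


def brute_up_reg(genes, ordered):
    """Position-sum formula evaluated by explicit enumeration (oracle)."""
    positions = [ordered.index(g) + 1 for g in genes if g in ordered]
    n, G = len(positions), len(ordered)
    real = sum(positions)
    best = sum(range(1, n + 1))
    worst = sum(range(G - n + 1, G + 1))
    return 100 - 200 * (real - best) / (worst - best)


def brute_co_reg(predicted, ordered, n_hits):
    positions = [ordered.index(g) + 1 for g in predicted if g in ordered]
    m, G = len(positions), len(ordered)
    real = sum(positions)
    best = sum(range(n_hits + 1, n_hits + m + 1))
    worst = sum(range(G - m + 1, G + 1))
    return 100 - 200 * (real - best) / (worst - best)


GENES10 = tuple(f"g{i}" for i in range(10))


class TestCoRegScore:
    def test_ideal_block_scores_100(self):
        ranking = toy_ranking(GENES10)
        result = cx.co_reg_score(["g3", "g4"], ranking, n_hits=3)
        assert result.score == 100.0

    def test_bottom_block_scores_minus_100(self):
        ranking = toy_ranking(GENES10)
        result = cx.co_reg_score(["g8", "g9"], ranking, n_hits=3)
        assert result.score == -100.0

    def test_worked_example_positions_4_and_7(self):
        ranking = toy_ranking(GENES10)
        result = cx.co_reg_score(["g3", "g6"], ranking, n_hits=3)  # positions 4, 7
        assert (result.added_real, result.added_best, result.added_worst) == (11, 9, 19)
        assert result.score == pytest.approx(brute_co_reg(["g3", "g6"], list(GENES10), 3))
        assert result.score == pytest.approx(100 - 200 * (11 - 9) / (19 - 9))

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            cx.co_reg_score([], toy_ranking(GENES10), 3)

    def test_degenerate_ranking_rejected(self):
        ranking = toy_ranking(("a", "b", "c"))
        with pytest.raises(ValueError):
            cx.co_reg_score(["b", "c"], ranking, n_hits=1)


class TestUpRegScore:
    def test_top_block_scores_100(self):
        assert cx.up_reg_score({"g0", "g1", "g2"}, toy_ranking(GENES10)).score == 100.0

    def test_bottom_block_scores_minus_100(self):
        assert cx.up_reg_score({"g7", "g8", "g9"}, toy_ranking(GENES10)).score == -100.0

    def test_worked_example_positions_1_5_10(self):
        result = cx.up_reg_score({"g0", "g4", "g9"}, toy_ranking(GENES10))
        assert (result.added_real, result.added_best, result.added_worst) == (16, 6, 27)
        assert result.score == pytest.approx(100 - 200 * (16 - 6) / (27 - 6))

    def test_omitted_genes_shrink_n(self):
        result = cx.up_reg_score({"g0", "g1", "nope"}, toy_ranking(GENES10))
        assert result.n_evaluated == 2
        assert result.omitted == ("nope",)
        assert result.score == 100.0  # the two found genes occupy the top

    def test_all_omitted_rejected(self):
        with pytest.raises(ValueError):
            cx.up_reg_score({"nope"}, toy_ranking(GENES10))

    @given(
        g=st.integers(4, 8),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry_under_ranking_reversal(self, g, data):
        ordered = tuple(f"x{i}" for i in range(g))
        subset = data.draw(
            st.sets(st.sampled_from(ordered), min_size=1, max_size=g - 1)
        )
        fwd = cx.up_reg_score(subset, toy_ranking(ordered)).score
        rev = cx.up_reg_score(subset, toy_ranking(ordered[::-1])).score
        assert fwd == pytest.approx(-rev)

    def test_monotone_in_positions(self):
        ordered = list(GENES10)
        base = cx.up_reg_score({"g5"}, toy_ranking(ordered)).score
        ordered.remove("g5")
        ordered.insert(2, "g5")  # strictly better position
        improved = cx.up_reg_score({"g5"}, toy_ranking(ordered)).score
        assert improved > base

    def test_invariant_to_relabeling_outside_set(self):
        ordered = list(GENES10)
        score = cx.up_reg_score({"g2", "g6"}, toy_ranking(ordered)).score
        relabeled = ["z" + g if g not in {"g2", "g6"} else g for g in ordered]
        assert cx.up_reg_score({"g2", "g6"}, toy_ranking(relabeled)).score == score


class TestBruteForceEquivalence:
    """Both scores match exhaustive position-sum enumeration for small G."""

    @pytest.mark.parametrize("g", [4, 6, 8])
    def test_up_reg_all_subsets(self, g):
        ordered = [f"g{i}" for i in range(g)]
        ranking = toy_ranking(ordered)
        for r in range(1, g):
            for subset in itertools.combinations(ordered, r):
                expected = brute_up_reg(subset, ordered)
                assert cx.up_reg_score(set(subset), ranking).score == pytest.approx(expected)

    @pytest.mark.parametrize("g", [5, 7, 8])
    def test_co_reg_all_subsets_and_hit_counts(self, g):
        ordered = [f"g{i}" for i in range(g)]
        ranking = toy_ranking(ordered)
        for n_hits in range(0, g - 1):
            candidates = ordered[n_hits:]
            for r in range(1, min(3, g - n_hits)):
                for subset in itertools.combinations(candidates, r):
                    if n_hits + len(subset) >= g:
                        continue
                    expected = brute_co_reg(list(subset), ordered, n_hits)
                    got = cx.co_reg_score(list(subset), ranking, n_hits).score
                    assert got == pytest.approx(expected)


class TestClusterProfile:
    def test_single_cluster_matches_direct_score(self, small_world, small_db, up_ranking):
        hits = list(small_world.members("up_shared"))
        net = cx.build_network(hits, small_db)
        clusters = cx.assign_clusters(net, min_size=3)
        matrix, cells = cx.cluster_profile(clusters, [("main", up_ranking)])
        lab = clusters.numbered_labels()[0]
        direct = cx.up_reg_score(clusters.members(lab), up_ranking).score
        assert matrix.loc[lab, "main"] == pytest.approx(direct)
        assert cells[(lab, "main")].score == pytest.approx(direct)

    def test_fully_absent_cluster_flagged(self):
        ranking = toy_ranking(GENES10)
        clusters = cx.ClusterAssignment(labels={"q1": "1", "q2": "1"}, min_size=1)
        matrix, cells = cx.cluster_profile(clusters, [("main", ranking)])
        assert np.isnan(matrix.loc["1", "main"])
        assert cells[("1", "main")] is None

    def test_planted_shared_vs_private_module(self, small_world, small_db):
        """A module upregulated in both experiments scores high in both; a
        module regulated only in 'main' scores near zero in the companion."""
        comp = cx.rank_genes(
            cx.average_replicates(cx.emit_expression(small_world, "companion")), "up"
        )
        main = cx.rank_genes(
            cx.average_replicates(cx.emit_expression(small_world, "main")), "up"
        )
        shared = set(small_world.members("up_shared"))
        private = set(small_world.members("up_private"))
        assert cx.up_reg_score(shared, main).score > 90
        assert cx.up_reg_score(shared, comp).score > 90
        assert cx.up_reg_score(private, main).score > 90
        assert abs(cx.up_reg_score(private, comp).score) < 30


class TestProjection:
    def test_identity_projection_matches_original(self, small_world, small_db, main_summaries):
        hits = list(small_world.members("up_shared"))
        net = cx.build_network(hits, small_db)
        frame = cx.project_experiment(net, main_summaries)
        means = {s.gene: s.mean for s in main_summaries}
        for gene in net.graph.nodes:
            assert frame.loc[gene, "mean_log2_diff"] == pytest.approx(means[gene])
            assert frame.loc[gene, "color_bin"] == cx.color_bin(means[gene])
            assert not frame.loc[gene, "omitted"]

    def test_missing_node_flagged_omitted(self, small_world, small_db, main_summaries):
        hits = list(small_world.members("up_shared"))
        net = cx.build_network(hits, small_db)
        partial = {s.gene: s.mean for s in main_summaries if s.gene != hits[0]}
        frame = cx.project_experiment(net, partial)
        assert frame.loc[hits[0], "omitted"]
        assert frame.loc[hits[0], "color_bin"] == "NA"
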