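"""Rank aggregation: SNP ranks, pair scores, gene scores, top-2% selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epinet.aggregation import (GenePairScore, RankMatrix, inter_gene,
                                inter_snp, n_gene_pairs, n_selected,
                                rank_matrix, rank_scores, select_top_pairs,
                                snp_pair_score_bounds)
from epinet.epistasis import ScoreMatrix


class TestRankScores:
    def test_two_candidates(self):
        np.testing.assert_array_equal(
            rank_scores(np.array([0.5, 0.2]), np.array([2, 3])), [1, 2])

    def test_all_zero_row_is_index_order(self):
        ranks = rank_scores(np.zeros(5), np.array([10, 11, 12, 13, 14]))
        np.testing.assert_array_equal(ranks, [1, 2, 3, 4, 5])

    def test_tie_broken_by_ascending_index(self):
        ranks = rank_scores(np.array([0.1, 0.9, 0.1]), np.array([4, 5, 6]))
        np.testing.assert_array_equal(ranks, [2, 1, 3])

    @given(st.lists(st.floats(0, 10), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_is_permutation(self, scores):
        s = np.array(scores)
        ranks = rank_scores(s, np.arange(s.size))
        assert sorted(ranks) == list(range(1, s.size + 1))


class TestInterSnp:
    def test_best_reciprocal_pair(self):
        assert inter_snp(1, 1) == pytest.approx(1 / math.sqrt(2))

    def test_printed_lower_bound_at_p_1000(self):
        assert inter_snp(999, 999) == pytest.approx(1 / math.sqrt(1998))
        assert round(inter_snp(999, 999), 2) == 0.02

    @given(st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_monotonicity(self, r1, r2):
        assert inter_snp(r1, r2) == inter_snp(r2, r1)
        assert inter_snp(r1 + 1, r2) < inter_snp(r1, r2)

    def test_rank_below_one_errors(self):
        with pytest.raises(ValueError):
            inter_snp(0, 3)


def _rank_matrix_from_rows(rows):
    """RankMatrix over p SNPs from explicit rank rows (0 on the diagonal)."""
    rows = np.asarray(rows, dtype=float)
    return RankMatrix(np.arange(rows.shape[0]), rows, set())


class TestInterGene:
    def test_singleton_genes_reduce_to_snp_score(self):
        ranks = _rank_matrix_from_rows([[0, 2, 1], [1, 0, 2], [2, 1, 0]])
        gp = inter_gene(ranks, "A", frozenset({0}), "B", frozenset({2}))
        assert gp.score == pytest.approx(inter_snp(1, 2))
        assert (gp.best_snp_a, gp.best_snp_b) == (0, 2)

    def test_hand_evaluation_of_cross_product_mean(self):
        # G1 = {s0, s1}, G2 = {s2}; r(0,2)=2, r(2,0)=1, r(1,2)=4, r(2,1)=3
        # on p=5 SNPs -> (1/sqrt(3) + 1/sqrt(7)) / 2
        rows = np.array([
            [0, 1, 2, 3, 4],
            [1, 0, 4, 2, 3],
            [1, 3, 0, 2, 4],
            [1, 2, 3, 0, 4],
            [1, 2, 3, 4, 0],
        ], dtype=float)
        rm = _rank_matrix_from_rows(rows)
        gp = inter_gene(rm, "G1", frozenset({0, 1}), "G2", frozenset({2}))
        assert gp.score == pytest.approx((1 / math.sqrt(3) + 1 / math.sqrt(7)) / 2)
        assert gp.score == pytest.approx(0.47766, abs=5e-5)
        assert (gp.best_snp_a, gp.best_snp_b) == (0, 2)

    def test_invariant_under_snp_relabeling_within_gene(self):
        rng = np.random.default_rng(0)
        p = 6
        rows = np.zeros((p, p))
        for i in range(p):
            perm = rng.permutation(p - 1) + 1
            rows[i, np.arange(p) != i] = perm
        rm = _rank_matrix_from_rows(rows)
        a, b = frozenset({0, 1, 2}), frozenset({4, 5})
        s1 = inter_gene(rm, "A", a, "B", b).score
        s2 = inter_gene(rm, "A", frozenset({2, 0, 1}), "B", frozenset({5, 4})).score
        assert s1 == pytest.approx(s2)

    def test_shared_snp_excluded_from_both_sides(self):
        ranks = _rank_matrix_from_rows([[0, 2, 1], [1, 0, 2], [2, 1, 0]])
        gp = inter_gene(ranks, "A", frozenset({0, 1}), "B", frozenset({1, 2}))
        # SNP 1 removed from both: reduces to the {0} x {2} singleton score
        assert gp.score == pytest.approx(inter_snp(1, 2))

    def test_fully_shared_pair_skipped(self):
        ranks = _rank_matrix_from_rows([[0, 2, 1], [1, 0, 2], [2, 1, 0]])
        assert inter_gene(ranks, "A", frozenset({1}), "B", frozenset({1})) is None


class TestRankMatrixFromScores:
    def _score_matrix(self, seed=0, p=6):
        rng = np.random.default_rng(seed)
        scores = rng.random((p, p)) * (rng.random((p, p)) < 0.4)
        np.fill_diagonal(scores, np.nan)
        return ScoreMatrix(np.arange(p), scores)

    def test_index_rows_are_permutations(self):
        rm = rank_matrix(self._score_matrix(), tie_method="index")
        p = rm.p
        for i in range(p):
            assert sorted(np.delete(rm.ranks[i], i)) == list(range(1, p))

    def test_midrank_rows_preserve_rank_sum_and_order(self):
        sm = self._score_matrix(seed=3)
        rm = rank_matrix(sm, tie_method="midrank")
        p = rm.p
        for i in range(p):
            row = np.delete(rm.ranks[i], i)
            assert row.sum() == pytest.approx(p * (p - 1) / 2)
            # larger score -> strictly smaller rank
            s = np.delete(np.nan_to_num(sm.scores[i]), i)
            order = np.argsort(-s, kind="stable")
            assert (np.diff(row[order]) >= 0).all()

    def test_random_tie_method_deterministic_under_seed(self):
        sm = self._score_matrix(seed=5)
        r1 = rank_matrix(sm, tie_method="random", seed=9)
        r2 = rank_matrix(sm, tie_method="random", seed=9)
        np.testing.assert_array_equal(r1.ranks, r2.ranks)


def test_pair_scores_within_bounds():
    rng = np.random.default_rng(1)
    p = 12
    rows = np.zeros((p, p))
    for i in range(p):
        rows[i, np.arange(p) != i] = rng.permutation(p - 1) + 1
    rm = _rank_matrix_from_rows(rows)
    lo, hi = snp_pair_score_bounds(p)
    for i in range(p):
        for j in range(i + 1, p):
            s = inter_snp(rm.ranks[i, j], rm.ranks[j, i])
            assert lo <= s <= hi
    assert hi == pytest.approx(1 / math.sqrt(2))


class TestSelection:
    def test_gene_pair_count(self):
        assert n_gene_pairs(38) == 703

    @pytest.mark.parametrize("n_pairs,k", [(703, 14), (45, 1), (210, 4),
                                           (630, 13), (276, 6), (406, 8)])
    def test_half_up_rounding(self, n_pairs, k):
        assert n_selected(n_pairs) == k

    def test_floor_of_one_edge(self):
        assert n_selected(10) == 1

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            n_selected(100, fraction=0.0)

    def test_select_top_pairs_orders_and_truncates(self):
        pairs = [GenePairScore(f"g{i}", f"h{i}", s, 0, 1, s)
                 for i, s in enumerate([0.1, 0.5, 0.3, 0.2] + [0.05] * 96)]
        top = select_top_pairs(pairs, fraction=0.02)
        assert len(top) == 2
        assert [p.score for p in top] == [0.5, 0.3]

    def test_cutoff_ties_broken_lexicographically(self):
        pairs = [GenePairScore("gB", "gC", 0.2, 0, 1, 0.2),
                 GenePairScore("gA", "gD", 0.2, 0, 1, 0.2)]
        top = select_top_pairs(pairs, fraction=0.5)
        assert top[0].genes == ("gA", "gD")
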