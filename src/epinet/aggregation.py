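"""Rank aggregation: SNP-level interaction scores to gene-gene scores.

Within each target's score row, candidates are ranked in decreasing score
order (rank 1 = strongest).  Two opposite ranks combine into the symmetric
SNP-pair score 1/sqrt(r_ij + r_ji), bounded between 1/sqrt(2(p-1)) and
1/sqrt(2); averaging the pair scores over the SNP-set cross product of two
genes gives a gene-pair score that is insensitive to gene size.  The top 2%
of gene pairs per map (nearest integer, at least one) form the epistatic
edge list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .epistasis import ScoreMatrix
from .mapping import SnpGeneMap

logger = logging.getLogger(__name__)


def rank_scores(score_row: np.ndarray, candidate_indices: np.ndarray) -> np.ndarray:
    """Ranks of one target's candidate scores, decreasing, ties by SNP index.

    The highest score gets rank 1; equal scores (pervasive with sparse fits,
    whose zero block ties) are broken deterministically by ascending SNP
    index.  The output is a permutation of {1, ..., len(scores)}.
    """
    s = np.asarray(score_row, dtype=float)
    idx = np.asarray(candidate_indices)
    if s.shape != idx.shape:
        raise ValueError("scores and candidate indices must align")
    if (s < 0).any():
        raise ValueError("scores must be non-negative")
    order = np.lexsort((idx, -s))  # decreasing score, then ascending index
    ranks = np.empty(s.size, dtype=int)
    ranks[order] = np.arange(1, s.size + 1)
    return ranks


@dataclass
class RankMatrix:
    """Within-target ranks r_ij for every ordered pair of mapped SNPs.

    ``ranks[i, j]`` is the rank of candidate j in target i's row, in
    [1, p-1]; the diagonal is 0 (absent).  With a permutation tie rule every
    row is a permutation of {1, ..., p-1}; with midranks, tied candidates
    share the mean of the ranks they span (rows then sum to the same total).
    """

    snp_indices: np.ndarray
    ranks: np.ndarray
    degenerate: set[int]

    @property
    def p(self) -> int:
        return int(self.snp_indices.size)

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)
        self.ranks = np.asarray(self.ranks, dtype=float)
        p = self.p
        total = p * (p - 1) // 2
        for i in range(p):
            row = np.delete(self.ranks[i], i)
            if row.min() < 1 or row.max() > p - 1 or \
                    not np.isclose(row.sum(), total):
                raise ValueError(f"rank row {i} is not a valid ranking of "
                                 f"1..p-1")


def rank_matrix(sm: ScoreMatrix, tie_method: str = "midrank",
                seed: int = 0) -> RankMatrix:
    """Rank every target row of a score matrix, decreasing.

    Sparse fits tie many candidates at score zero.  Tied scores carry no
    ordering evidence, so the default gives them midranks (the mean of the
    rank span they share, the standard treatment of ties): arbitrary tie
    order then cannot inject noise into gene-level averages.  Two
    permutation rules are kept as alternatives: ``"index"`` (ascending SNP
    index, fully deterministic) and ``"random"`` (seeded pseudo-random key
    per row, deterministic under the seed and unbiased).
    Degenerate targets carry all-zero rows; any tie rule still yields valid
    rankings, and the targets stay flagged.
    """
    from scipy.stats import rankdata

    p = sm.p
    ranks = np.zeros((p, p), dtype=float)
    for i in range(p):
        cand = np.delete(np.arange(p), i)
        row = sm.scores[i, cand]
        row = np.where(np.isnan(row), 0.0, row)
        if tie_method == "midrank":
            rr = rankdata(-row, method="average")
        elif tie_method in ("index", "random"):
            if tie_method == "index":
                key = sm.snp_indices[cand]
            else:
                key = np.random.default_rng((seed, i)).permutation(cand.size)
            order = np.lexsort((key, -row))
            rr = np.empty(cand.size, dtype=float)
            rr[order] = np.arange(1, cand.size + 1)
        else:
            raise ValueError(f"unknown tie_method {tie_method!r}")
        ranks[i, cand] = rr
    return RankMatrix(sm.snp_indices, ranks, set(sm.degenerate))


def inter_snp(r_ij: float, r_ji: float) -> float:
    """Symmetric SNP-pair interaction score 1/sqrt(r_ij + r_ji).

    Ranks may be integers (permutation tie rule) or midranks; both start
    at 1.
    """
    if r_ij < 1 or r_ji < 1:
        raise ValueError("ranks start at 1")
    return 1.0 / math.sqrt(r_ij + r_ji)


def snp_pair_score_bounds(p: int) -> tuple[float, float]:
    """(min, max) attainable SNP-pair score with p mapped SNPs."""
    return 1.0 / math.sqrt(2 * (p - 1)), 1.0 / math.sqrt(2)


@dataclass
class GenePairScore:
    """Symmetric interaction score of one gene pair.

    ``best_snp_a``/``best_snp_b`` are the global SNP column indices of the
    top-scoring SNP pair inside the cross product (the pair driving the
    score), used downstream for the missense filter and direction fit.
    """

    gene_a: str
    gene_b: str
    score: float
    best_snp_a: int
    best_snp_b: int
    best_pair_score: float

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
            self.best_snp_a, self.best_snp_b = self.best_snp_b, self.best_snp_a

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def inter_gene(rm: RankMatrix, gene_a: str, snps_a: frozenset[int],
               gene_b: str, snps_b: frozenset[int]) -> GenePairScore | None:
    """Gene-pair score: mean SNP-pair score over the cross product.

    A SNP mapped to both genes of the pair is excluded from both sets for
    this pair (self-pairs are never scored); if either set empties, the pair
    is skipped with a warning.
    """
    shared = snps_a & snps_b
    if shared:
        logger.info("gene pair (%s, %s): %d shared SNPs excluded from both "
                    "sides", gene_a, gene_b, len(shared))
    a = sorted(snps_a - shared)
    b = sorted(snps_b - shared)
    if not a or not b:
        logger.warning("gene pair (%s, %s) has no disjoint SNPs; skipped",
                       gene_a, gene_b)
        return None
    pos = {int(j): r for r, j in enumerate(rm.snp_indices)}
    total = 0.0
    best = (-1.0, -1, -1)
    for i in a:
        for j in b:
            ri, rj = pos[i], pos[j]
            s = inter_snp(rm.ranks[ri, rj], rm.ranks[rj, ri])
            total += s
            if s > best[0] or (s == best[0] and (i, j) < best[1:]):
                best = (s, i, j)
    score = total / (len(a) * len(b))
    return GenePairScore(gene_a, gene_b, score, best[1], best[2], best[0])


def gene_pair_scores(rm: RankMatrix, snp_map: SnpGeneMap) -> list[GenePairScore]:
    """All within-map gene-pair scores, sorted lexicographically by pair."""
    genes = sorted(snp_map.genes)
    out = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            gp = inter_gene(rm, ga, snp_map.genes[ga], gb, snp_map.genes[gb])
            if gp is not None:
                out.append(gp)
    return out


def n_gene_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs p'(p'-1)/2."""
    return math.comb(n_genes, 2)


def n_selected(n_pairs: int, fraction: float = 0.02) -> int:
    """Edge count retained by the top-fraction rule.

    Nearest integer (half rounds up) of fraction * n_pairs, with a floor of
    one edge so every map keeps at least one pair.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    k = math.floor(fraction * n_pairs + 0.5)
    if k == 0:
        logger.info("top-%g%% of %d pairs rounds to 0; keeping 1", 100 * fraction,
                    n_pairs)
        k = 1
    return k


def select_top_pairs(gene_scores: list[GenePairScore],
                     fraction: float = 0.02) -> list[GenePairScore]:
    """The top-scoring fraction of gene pairs (the epistatic edge list).

    Ties at the cutoff are broken by score then lexicographic gene pair.
    """
    if not gene_scores:
        raise ValueError("no scored gene pairs")
    k = n_selected(len(gene_scores), fraction)
    ordered = sorted(gene_scores, key=lambda g: (-g.score, g.genes))
    return ordered[:k]
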