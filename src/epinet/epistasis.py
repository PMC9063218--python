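"""Targeted interaction scoring via the propensity-weighted modified outcome.

For a binary target state A-tilde with propensity pi = P(A-tilde=1 | X) and a
signed phenotype y in {-1, +1}, the modified outcome

    y_tilde = y * (a_tilde / pi - (1 - a_tilde) / (1 - pi))

has conditional mean 2 * delta(X), where delta(X) is the interaction
component of the phenotype decomposition y = mu(X) + delta(X) * A + noise.
A sparse elastic-net fit of y_tilde on the candidate genotypes therefore
scores each candidate's interaction with the target; the robust variant
self-normalizes the inverse-propensity weights arm-wise (Hajek weighting)
to tame variance when propensities are imperfect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .gwas_io import GenotypeData
from .hmm import HaplotypeClusterModel, binarize_target, propensity_scores
from .mapping import SnpGeneMap

logger = logging.getLogger(__name__)


@dataclass
class ModifiedOutcome:
    """Per-sample transformed phenotype, plain or robust variant."""

    values: np.ndarray
    variant: str  # "plain" | "robust"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("modified outcome contains non-finite values")


@dataclass
class TargetScores:
    """Interaction scores of every candidate SNP against one target."""

    target: int
    candidates: np.ndarray
    scores: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.candidates = np.asarray(self.candidates, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("scores are absolute coefficients, must be >= 0")
        if self.target in set(self.candidates.tolist()):
            raise ValueError("candidate set must exclude the target")


def _check_mo_inputs(y, a_tilde, pi):
    y = np.asarray(y, dtype=float)
    a = np.asarray(a_tilde, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if not np.isin(y, (-1.0, 1.0)).all():
        raise ValueError("phenotype must be signed: -1 (control) / +1 (case)")
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("target state must be binary 0/1")
    if ((pi <= 0.0) | (pi >= 1.0)).any():
        raise ValueError("propensities must lie strictly inside (0, 1); "
                         "clip upstream")
    return y, a, pi


def modified_outcome(y, a_tilde, pi) -> ModifiedOutcome:
    """Plain inverse-propensity modified outcome."""
    y, a, pi = _check_mo_inputs(y, a_tilde, pi)
    vals = y * (a / pi - (1.0 - a) / (1.0 - pi))
    return ModifiedOutcome(vals, "plain")


def robust_modified_outcome(y, a_tilde, pi) -> ModifiedOutcome:
    """Self-normalized (Hajek) modified outcome.

    The treated weights a/pi and control weights (1-a)/(1-pi) are each
    divided by their sample mean over all individuals, so both normalized
    weight sets average to 1.  With constant pi equal to the empirical arm
    share this reduces exactly to the plain variant.
    """
    y, a, pi = _check_mo_inputs(y, a_tilde, pi)
    w1 = a / pi
    w0 = (1.0 - a) / (1.0 - pi)
    if w1.sum() == 0 or w0.sum() == 0:
        raise ValueError("degenerate target: one arm of the binarized state "
                         "is empty")
    vals = y * (w1 / w1.mean() - w0 / w0.mean())
    return ModifiedOutcome(vals, "robust")


def fit_interaction_scores(
    candidates_X: np.ndarray,
    y_tilde: np.ndarray | ModifiedOutcome,
    l1_ratio: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
    target: int = -1,
    candidates: np.ndarray | None = None,
    alphas: int | list[float] = 50,
) -> TargetScores:
    """Elastic-net interaction scores for one target.

    Candidate columns are standardized; the penalty is chosen by k-fold
    cross-validated mean squared error with seeded folds (``alphas`` may be
    a grid size or an explicit list, e.g. a single fixed penalty).  Scores are the
    absolute fitted coefficients (sign is not used for ranking); constant
    columns are dropped with a warning and scored 0.
    """
    X = np.asarray(candidates_X, dtype=float)
    y = y_tilde.values if isinstance(y_tilde, ModifiedOutcome) else np.asarray(y_tilde, dtype=float)
    n, p = X.shape
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} samples for {n_folds}-fold CV")
    if candidates is None:
        candidates = np.arange(p)

    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d constant candidate columns dropped (score 0)",
                       int((~keep).sum()))
    scores = np.zeros(p)
    if keep.any():
        Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        enet = ElasticNetCV(
            l1_ratio=l1_ratio, alphas=alphas, cv=cv, fit_intercept=True,
            max_iter=5000, tol=1e-5,
        )
        enet.fit(Xs, y)
        scores[keep] = np.abs(enet.coef_)
        meta = {"penalty": float(enet.alpha_), "l1_ratio": l1_ratio,
                "folds": n_folds, "seed": seed}
    else:
        meta = {"penalty": None, "l1_ratio": l1_ratio, "folds": n_folds,
                "seed": seed}
    return TargetScores(target=target, candidates=np.asarray(candidates),
                        scores=scores, meta=meta)


@dataclass
class ScoringConfig:
    """Knobs of the per-target scoring stage."""

    l1_ratio: float = 0.5
    n_folds: int = 5
    variant: str = "robust"  # "plain" | "robust"
    encoding: str = "dominant"
    propensity_mode: str = "both"
    eps: float = 0.01
    alphas: int | list[float] = 50
    seed: int = 0


@dataclass
class ScoreMatrix:
    """Per-target interaction scores for every mapped SNP of a disease map.

    ``snp_indices`` are the mapped SNPs' global column indices; ``scores`` is
    (p_m, p_m) with NaN on the diagonal (a target is never its own
    candidate).  Rows of degenerate targets (binarized state constant) are
    all-zero and listed in ``degenerate``.
    """

    snp_indices: np.ndarray
    scores: np.ndarray
    degenerate: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        pm = self.snp_indices.size
        if self.scores.shape != (pm, pm):
            raise ValueError("score matrix must be square over mapped SNPs")

    @property
    def p(self) -> int:
        return int(self.snp_indices.size)


def score_all_targets(
    gd: GenotypeData,
    snp_map: SnpGeneMap,
    models: dict[str, HaplotypeClusterModel],
    config: ScoringConfig | None = None,
) -> ScoreMatrix:
    """Loop the modified-outcome fit over every mapped SNP as target.

    Candidates are all other mapped SNPs of the disease map.  Each target's
    propensity comes from its chromosome's haplotype-cluster model; the
    phenotype is signed (+1 case / -1 control).  Degenerate targets are
    flagged and given an all-zero row.
    """
    if config is None:
        config = ScoringConfig()
    if gd.phenotype is None:
        raise ValueError("scoring requires a phenotyped cohort")
    mapped = snp_map.mapped_snps
    pm = mapped.size
    if pm < 2:
        raise ValueError("need at least two mapped SNPs")
    M = gd.imputed_matrix()
    y_signed = 2.0 * gd.phenotype - 1.0

    chrom_sites = gd.chromosomes()
    site_in_chrom = {}
    for chrom, idx in chrom_sites.items():
        for local, j in enumerate(idx):
            site_in_chrom[int(j)] = (chrom, local)

    scores = np.full((pm, pm), np.nan)
    degenerate: set[int] = set()
    pos_of = {int(j): r for r, j in enumerate(mapped)}
    for r, j in enumerate(mapped):
        j = int(j)
        col = M[:, j].astype(int)
        a = binarize_target(col, config.encoding)
        if a.min() == a.max():
            degenerate.add(j)
            scores[r] = 0.0
            scores[r, r] = np.nan
            logger.warning("target SNP %s degenerate after binarization; "
                           "all-zero score row", gd.snps[j].id)
            continue
        chrom, local = site_in_chrom[j]
        model = models.get(chrom)
        if model is None:
            raise KeyError(f"no fitted model for chromosome {chrom!r}")
        pi = propensity_scores(model, M[:, chrom_sites[chrom]].astype(int),
                               local, encoding=config.encoding,
                               mode=config.propensity_mode, eps=config.eps)
        if config.variant == "robust":
            mo = robust_modified_outcome(y_signed, a, pi)
        else:
            mo = modified_outcome(y_signed, a, pi)
        cand = np.array([int(k) for k in mapped if int(k) != j])
        # per-target fold seeds: sharing one CV split across targets would
        # correlate penalty selection (and hence coefficient noise) between
        # rows, inflating spurious reciprocal top-ranks
        ts = fit_interaction_scores(
            M[:, cand], mo, l1_ratio=config.l1_ratio, n_folds=config.n_folds,
            seed=config.seed + 7919 * (r + 1), target=j, candidates=cand,
            alphas=config.alphas,
        )
        for k, s in zip(cand, ts.scores):
            scores[r, pos_of[int(k)]] = s
        scores[r, r] = np.nan
    return ScoreMatrix(mapped, scores, degenerate)
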