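"""Direction of the epistatic effect for selected gene pairs.

For each selected gene pair, the top-scoring SNP pair (x1, x2) enters the
logistic interaction model

    logit P(Y = 1 | x1, x2) = a0 + a1*x1 + a2*x2 + a12*x1*x2

with additive allele-count coding.  On the gene-expression scale — each SNP
acting on its gene's expression through e_i = gamma_i + beta_i * x_i, with
beta_i recovered from the eQTL Z-score — the interaction of the two
expression levels is governed by a12 / (beta1 * beta2); its sign is the
direction of the epistatic effect.  The same-sign rule keeps pairs where
beta1, beta2 and a12 (the synergy coefficient) are all positive ("inhibit
both" lowers risk) or all negative ("activate both" lowers risk).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: absolute coefficient beyond which a logistic fit is treated as separated
SEPARATION_THRESHOLD = 15.0


def fit_logistic_interaction(
    y01: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood fit of the two-SNP logistic interaction model.

    Returns ``(alphas, converged)`` with alphas = (a0, a1, a2, a12).
    ``converged`` is False under (quasi-)separation — detected either by the
    optimizer or by a coefficient exceeding ``SEPARATION_THRESHOLD`` — in
    which case the coefficients are unusable and the pair should be flagged.
    Optional case weights support fits on aggregated genotype cells.
    """
    y = np.asarray(y01, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("phenotype must be coded 0/1")
    for name, x in (("x1", x1), ("x2", x2)):
        if np.ptp(x) == 0:
            raise ValueError(f"predictor {name} is constant")
    X = np.column_stack([np.ones_like(x1), x1, x2, x1 * x2])
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=weights)
    try:
        res = model.fit(maxiter=200, tol=1e-10)
        converged = bool(res.converged)
        coef = np.asarray(res.params)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        logger.warning("logistic fit failed: %s", exc)
        return np.full(4, np.nan), False
    if not np.isfinite(coef).all() or np.abs(coef).max() > SEPARATION_THRESHOLD:
        converged = False
    return coef, converged


def direction(alpha12: float, beta1: float, beta2: float) -> int:
    """Sign of alpha12 / (beta1 * beta2): the direction of the epistasis.

    Invariant under flipping the signs of both betas.  Raises if any
    argument is zero or non-finite (undefined direction; the caller flags
    and excludes the pair).
    """
    vals = (alpha12, beta1, beta2)
    if not all(np.isfinite(v) for v in vals) or any(v == 0 for v in vals):
        raise ValueError("direction undefined: zero or non-finite coefficient")
    return int(np.sign(alpha12) * np.sign(beta1) * np.sign(beta2))


@dataclass
class DirectionResult:
    """Fitted direction of one gene pair's epistatic effect."""

    gene_a: str
    gene_b: str
    snp_a: str
    snp_b: str
    alphas: np.ndarray  # (a0, a1, a2, a12)
    beta1: float
    beta2: float
    converged: bool
    direction: int | None = None
    reading: str | None = None

    @property
    def alpha12(self) -> float:
        return float(self.alphas[3])

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if self.direction is None and self.converged:
            try:
                self.direction = direction(self.alpha12, self.beta1, self.beta2)
            except ValueError:
                self.direction = None


def evaluate_directions(
    pairs,
    genotype_matrix: np.ndarray,
    snp_ids: list[str],
    eqtl_beta: dict[tuple[str, str], float],
    y01: np.ndarray,
) -> list[DirectionResult]:
    """Fit the interaction model for each selected gene pair.

    ``pairs`` are scored gene pairs carrying their top SNP pair;
    ``eqtl_beta`` maps (snp_id, gene_id) to the eQTL-derived effect size.
    Pairs whose SNPs lack an eQTL effect for their gene get beta = NaN and an
    undefined direction.
    """
    out = []
    for pair in pairs:
        ja, jb = pair.best_snp_a, pair.best_snp_b
        sa, sb = snp_ids[ja], snp_ids[jb]
        b1 = eqtl_beta.get((sa, pair.gene_a), float("nan"))
        b2 = eqtl_beta.get((sb, pair.gene_b), float("nan"))
        try:
            alphas, converged = fit_logistic_interaction(
                y01, genotype_matrix[:, ja], genotype_matrix[:, jb]
            )
        except ValueError as exc:
            logger.warning("gene pair (%s, %s): %s", pair.gene_a, pair.gene_b, exc)
            alphas, converged = np.full(4, np.nan), False
        out.append(DirectionResult(
            gene_a=pair.gene_a, gene_b=pair.gene_b, snp_a=sa, snp_b=sb,
            alphas=alphas, beta1=float(b1), beta2=float(b2),
            converged=converged,
        ))
    return out


def same_sign_filter(results: list[DirectionResult]) -> list[DirectionResult]:
    """Keep pairs whose beta1, beta2 and synergy coefficient share a sign.

    All three strictly positive reads as "inhibit both" (joint inhibition
    lowers risk); all three strictly negative as "activate both".
    Non-converged fits and zero/NaN coefficients are excluded with a log
    entry.
    """
    kept = []
    for r in results:
        if not r.converged:
            logger.info("pair (%s, %s) excluded: fit did not converge",
                        r.gene_a, r.gene_b)
            continue
        trio = np.array([r.beta1, r.beta2, r.alpha12])
        if not np.isfinite(trio).all() or (trio == 0).any():
            logger.info("pair (%s, %s) excluded: undefined direction",
                        r.gene_a, r.gene_b)
            continue
        if (trio > 0).all():
            r.reading = "inhibit both"
        elif (trio < 0).all():
            r.reading = "activate both"
        else:
            continue
        kept.append(r)
    return kept
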