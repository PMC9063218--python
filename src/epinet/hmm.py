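"""Haplotype-cluster hidden Markov model and propensity scores.

The model is the classic mosaic model of haplotype structure: each haplotype
is a walk over K ancestral clusters.  At the first site of a chromosome the
cluster is drawn from weights alpha[0]; at site j the walk stays in its
cluster with probability 1 - rho[j] or jumps to cluster k with probability
rho[j] * alpha[j, k].  Cluster k emits the minor allele at site j with
frequency theta[j, k].  A diploid genotype is the sum of two independent
haplotype chains, so inference runs on the K x K product chain.

Fitting is by EM (Baum-Welch on the product chain); the per-site exchange of
messages uses the Kronecker structure of the pair transition, so each step
costs O(K^3) per sample rather than O(K^4).

The model's role in the epistasis pipeline is to supply propensity scores
for a target SNP: the probability that the target's binarized state is 1
given the remaining genotypes of the chromosome, read off the HMM predictive
distribution at the target site.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

THETA_FLOOR = 1e-4
RHO_FLOOR = 1e-6


@dataclass
class HaplotypeClusterModel:
    """Fitted mosaic model for the sites of one chromosome.

    alpha: (p, K) per-site cluster weights, each row sums to 1; alpha[0] is
      the initial cluster distribution and alpha[j] the jump destination
      weights at site j.
    rho: (p,) per-site jump probabilities in [0, 1]; rho[0] is unused.
    theta: (p, K) per-site, per-cluster minor-allele emission frequencies,
      clipped to [1e-4, 1 - 1e-4].
    """

    chrom: str
    snp_ids: list[str]
    alpha: np.ndarray
    rho: np.ndarray
    theta: np.ndarray
    loglik_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        p, k = self.alpha.shape
        if self.theta.shape != (p, k) or self.rho.shape != (p,):
            raise ValueError("inconsistent parameter shapes")
        if not np.allclose(self.alpha.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("cluster weights must sum to 1 at every site")
        if ((self.theta < THETA_FLOOR - 1e-12)
                | (self.theta > 1 - THETA_FLOOR + 1e-12)).any():
            raise ValueError("theta outside the clipped range")

    @property
    def n_sites(self) -> int:
        return self.alpha.shape[0]

    @property
    def K(self) -> int:
        return self.alpha.shape[1]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "chrom": self.chrom,
            "snp_ids": self.snp_ids,
            "K": self.K,
            "alpha": self.alpha.tolist(),
            "rho": self.rho.tolist(),
            "theta": self.theta.tolist(),
            "loglik_history": self.loglik_history,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "HaplotypeClusterModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            chrom=doc["chrom"],
            snp_ids=doc["snp_ids"],
            alpha=np.asarray(doc["alpha"]),
            rho=np.asarray(doc["rho"]),
            theta=np.asarray(doc["theta"]),
            loglik_history=list(doc.get("loglik_history", [])),
        )

    # -- generative sampling (used by the synthetic cohort generator) -------

    def sample_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n diploid genotype rows (two independent haplotype chains)."""
        p, K = self.theta.shape
        geno = np.zeros((n, p), dtype=np.int8)
        for _ in range(2):
            z = rng.choice(K, size=n, p=self.alpha[0])
            geno[:, 0] += rng.random(n) < self.theta[0, z]
            for j in range(1, p):
                jump = rng.random(n) < self.rho[j]
                z = np.where(jump, rng.choice(K, size=n, p=self.alpha[j]), z)
                geno[:, j] += rng.random(n) < self.theta[j, z]
        return geno


def _emission_tables(theta: np.ndarray) -> np.ndarray:
    """Per-site genotype emission probabilities, shape (p, 3, K, K).

    Entry [j, g, k1, k2] is P(genotype g at site j | clusters k1, k2):
    the two haplotype emissions are independent Bernoulli(theta).
    """
    t = theta  # (p, K)
    u = 1.0 - t
    e = np.empty((theta.shape[0], 3, theta.shape[1], theta.shape[1]))
    e[:, 0] = u[:, :, None] * u[:, None, :]
    e[:, 1] = t[:, :, None] * u[:, None, :] + u[:, :, None] * t[:, None, :]
    e[:, 2] = t[:, :, None] * t[:, None, :]
    return e


def _transition(alpha_j: np.ndarray, rho_j: float) -> np.ndarray:
    """Single-haplotype transition matrix into site j, shape (K, K)."""
    K = alpha_j.shape[0]
    return (1.0 - rho_j) * np.eye(K) + rho_j * alpha_j[None, :]


def _forward_backward(model: HaplotypeClusterModel, X: np.ndarray):
    """Scaled forward/backward messages on the K x K product chain.

    X: (n, p) genotypes in {0,1,2}.  Returns (F, B, c, E) with
    F, B of shape (n, p, K, K), scaling factors c of shape (n, p) and the
    per-sample emission tensors E of shape (n, p, K, K).  F[:, j] sums to 1;
    gamma_j = F_j * B_j.  log-likelihood per sample is sum_j log c_j.
    """
    n, p = X.shape
    K = model.K
    em = _emission_tables(model.theta)  # (p, 3, K, K)
    E = em[np.arange(p)[None, :], X, :, :]  # (n, p, K, K)

    F = np.empty((n, p, K, K))
    c = np.empty((n, p))
    init = np.outer(model.alpha[0], model.alpha[0])
    f = init[None, :, :] * E[:, 0]
    c[:, 0] = f.sum(axis=(1, 2))
    F[:, 0] = f / c[:, 0, None, None]
    for j in range(1, p):
        T = _transition(model.alpha[j], model.rho[j])
        pred = np.einsum("ka,nkl,lb->nab", T, F[:, j - 1], T, optimize=True)
        f = pred * E[:, j]
        c[:, j] = f.sum(axis=(1, 2))
        F[:, j] = f / c[:, j, None, None]

    B = np.empty((n, p, K, K))
    B[:, p - 1] = 1.0
    for j in range(p - 2, -1, -1):
        T = _transition(model.alpha[j + 1], model.rho[j + 1])
        G = E[:, j + 1] * B[:, j + 1]
        B[:, j] = np.einsum("ak,nkl,bl->nab", T, G, T, optimize=True) \
            / c[:, j + 1, None, None]
    return F, B, c, E


def loglik(model: HaplotypeClusterModel, X: np.ndarray) -> float:
    """Total observed-data log-likelihood of genotypes X under the model."""
    _, _, c, _ = _forward_backward(model, np.asarray(X, dtype=np.intp))
    return float(np.log(c).sum())


def _m_step(model, X, F, B, c, E):
    """One EM update; returns (alpha, rho, theta) new parameters."""
    n, p = X.shape
    K = model.K
    gamma = F * B  # (n, p, K, K); each [i, j] sums to 1
    gamma /= gamma.sum(axis=(2, 3), keepdims=True)

    # --- emissions: expected minor alleles emitted per (site, cluster) -----
    theta_new = np.empty((p, K))
    t = model.theta
    for j in range(p):
        g = gamma[:, j]  # (n, K, K)
        x = X[:, j]
        # E[h1 | g, k1, k2]: 0 for g=0, 1 for g=2; Bayes split for hets.
        th1 = t[j][:, None] * (1 - t[j])[None, :]
        th2 = (1 - t[j])[:, None] * t[j][None, :]
        h1_het = th1 / (th1 + th2)
        is_het = (x[:, None, None] == 1)
        is_hom2 = (x[:, None, None] == 2)
        w1 = np.where(is_hom2, 1.0, np.where(is_het, h1_het[None], 0.0))
        w2 = np.where(is_hom2, 1.0, np.where(is_het, 1.0 - h1_het[None], 0.0))
        num = (g * w1).sum(axis=(0, 2)) + (g * w2).sum(axis=(0, 1))
        den = g.sum(axis=(0, 2)) + g.sum(axis=(0, 1))
        theta_new[j] = np.where(den > 0, num / np.maximum(den, 1e-300), t[j])
    theta_new = np.clip(theta_new, THETA_FLOOR, 1.0 - THETA_FLOOR)

    # --- transitions: per-haplotype expected counts, then the jump split ---
    alpha_new = model.alpha.copy()
    rho_new = model.rho.copy()
    # initial distribution from site-0 haplotype marginals
    p1 = gamma[:, 0].sum(axis=(0, 2)) + gamma[:, 0].sum(axis=(0, 1))
    alpha_new[0] = p1 / p1.sum()
    for j in range(1, p):
        T = _transition(model.alpha[j], model.rho[j])
        # pair-chain transition posteriors marginalized to one haplotype:
        # C1(k,l) = T(k,l) * sum_i [F_{j-1} T G^T]_i(k,l) / c_j with
        # G = E_j * B_j; the Kronecker structure keeps this O(K^3).
        Gm = E[:, j] * B[:, j] / c[:, j, None, None]  # (n, K, K)
        M1 = np.einsum("nka,ab,nlb->kl", F[:, j - 1], T, Gm, optimize=True)
        M2 = np.einsum("nak,ab,nbl->kl", F[:, j - 1], T, Gm, optimize=True)
        C = T * (M1 + M2)
        total = C.sum()
        if total <= 0:
            continue
        # posterior probability that a k -> l move was a jump
        jump = model.rho[j] * np.broadcast_to(model.alpha[j][None, :], (K, K))
        p_jump = jump / np.maximum(T, 1e-300)
        J = C * p_jump
        rho_new[j] = float(np.clip(J.sum() / total, RHO_FLOOR, 1.0 - RHO_FLOOR))
        dest = J.sum(axis=0)
        if dest.sum() > 0:
            a = dest / dest.sum()
            alpha_new[j] = np.maximum(a, 1e-8)
            alpha_new[j] /= alpha_new[j].sum()
    return alpha_new, rho_new, theta_new


def fit_hmm(
    X: np.ndarray,
    K: int,
    n_iter: int = 25,
    seed: int = 0,
    chrom: str = "0",
    snp_ids: list[str] | None = None,
    n_restarts: int = 3,
    tol: float = 1e-6,
) -> HaplotypeClusterModel:
    """Fit the mosaic model to the genotypes of one chromosome by EM.

    ``X`` is (n_samples, p_sites) with entries in {0,1,2} (impute missing
    upstream).  The observed-data log-likelihood is non-decreasing across
    iterations; the best of ``n_restarts`` seeded random initializations is
    returned, with its log-likelihood trace in ``loglik_history``.
    """
    X = np.asarray(X, dtype=np.intp)
    if X.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    n, p = X.shape
    if K < 1 or n_iter < 1:
        raise ValueError("K and n_iter must be >= 1")
    if K > 2**p:
        logger.warning("K=%d exceeds the number of distinct haplotypes over "
                       "%d sites; fitting anyway", K, p)
    if snp_ids is None:
        snp_ids = [f"site{j}" for j in range(p)]
    freqs = X.mean(axis=0) / 2.0
    rng_master = np.random.default_rng(seed)

    best: HaplotypeClusterModel | None = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        alpha = np.full((p, K), 1.0 / K)
        rho = np.full(p, 0.05)
        theta = np.clip(
            freqs[:, None] + rng.normal(0, 0.1, size=(p, K)),
            THETA_FLOOR, 1.0 - THETA_FLOOR,
        )
        model = HaplotypeClusterModel(chrom, snp_ids, alpha, rho, theta)
        history: list[float] = []
        prev = -np.inf
        for _it in range(n_iter):
            F, B, c, E = _forward_backward(model, X)
            ll = float(np.log(c).sum())
            history.append(ll)
            a, r, t = _m_step(model, X, F, B, c, E)
            model = HaplotypeClusterModel(chrom, snp_ids, a, r, t)
            if ll - prev < tol and _it > 0:
                prev = ll
                break
            prev = ll
        model.loglik_history = history
        if best is None or history[-1] > best.loglik_history[-1]:
            best = model
    assert best is not None
    return best


def binarize_target(column: np.ndarray, encoding: str = "dominant") -> np.ndarray:
    """Binarize a genotype column into the target state A-tilde in {0, 1}.

    Dominant encoding sets 1 for >= 1 minor allele; recessive requires both.
    The signed state is A = 2*A_tilde - 1.  An all-constant column is a
    degenerate target (flagged by the caller).
    """
    column = np.asarray(column)
    if not np.isin(column, (0, 1, 2)).all():
        raise ValueError("genotype column must contain only 0/1/2")
    if encoding == "dominant":
        a = (column >= 1).astype(np.int8)
    elif encoding == "recessive":
        a = (column == 2).astype(np.int8)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    if len(set(a.tolist())) == 1:
        logger.warning("degenerate target: binarized state is constant")
    return a


def target_state_distribution(
    model: HaplotypeClusterModel,
    X: np.ndarray,
    target_index: int,
    mode: str = "both",
) -> np.ndarray:
    """Predictive genotype distribution at the target site, shape (n, 3).

    Conditions on the flanking sites of the chromosome: the forward message
    into the target is combined with the backward message out of it, neither
    including the target's own emission.  ``mode="forward"`` conditions on
    the left flank only.
    """
    X = np.asarray(X, dtype=np.intp)
    n, p = X.shape
    K = model.K
    if not (0 <= target_index < p):
        raise IndexError(f"target index {target_index} outside model sites")
    F, B, c, E = _forward_backward(model, X)

    if target_index == 0:
        pred = np.broadcast_to(
            np.outer(model.alpha[0], model.alpha[0])[None], (n, K, K)
        ).copy()
    else:
        T = _transition(model.alpha[target_index], model.rho[target_index])
        pred = np.einsum("ka,nkl,lb->nab", T, F[:, target_index - 1], T,
                         optimize=True)
    if mode == "both":
        post = pred * B[:, target_index]
    elif mode == "forward":
        post = pred
    else:
        raise ValueError(f"unknown propensity mode {mode!r}")
    post = post / post.sum(axis=(1, 2), keepdims=True)

    em = _emission_tables(model.theta[target_index:target_index + 1])[0]  # (3,K,K)
    dist = np.einsum("nkl,gkl->ng", post, em, optimize=True)
    return dist / dist.sum(axis=1, keepdims=True)


def propensity_scores(
    model: HaplotypeClusterModel,
    X: np.ndarray,
    target_index: int,
    encoding: str = "dominant",
    mode: str = "both",
    eps: float = 0.01,
) -> np.ndarray:
    """Per-sample propensity P(A-tilde = 1 | flanking genotypes).

    Computed from the HMM predictive genotype distribution at the target
    site and the binarization rule; clipped to [eps, 1-eps] to guard the
    inverse weighting downstream against numerical instability.
    """
    dist = target_state_distribution(model, X, target_index, mode=mode)
    if encoding == "dominant":
        pi = dist[:, 1] + dist[:, 2]
    elif encoding == "recessive":
        pi = dist[:, 2]
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return np.clip(pi, eps, 1.0 - eps)


def site_predictive_logloss(
    model: HaplotypeClusterModel, X: np.ndarray, sites: list[int] | None = None
) -> float:
    """Mean negative log P(observed genotype at site | rest of chromosome).

    A label-free measure of model quality: cluster labels are not
    identifiable, but held-out predictive probability is.
    """
    X = np.asarray(X, dtype=np.intp)
    n, p = X.shape
    if sites is None:
        sites = list(range(p))
    losses = []
    for t in sites:
        dist = target_state_distribution(model, X, t)
        probs = dist[np.arange(n), X[:, t]]
        losses.append(-np.log(np.maximum(probs, 1e-300)).mean())
    return float(np.mean(losses))
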