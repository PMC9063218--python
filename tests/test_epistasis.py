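"""Modified outcome construction and elastic-net interaction scoring."""

import numpy as np
import pytest

from epinet.epistasis import (ScoringConfig, fit_interaction_scores,
                              modified_outcome, robust_modified_outcome,
                              score_all_targets)
from epinet.hmm import fit_hmm
from epinet.mapping import SnpGeneMap


class TestModifiedOutcome:
    @pytest.mark.parametrize("y,a,pi,expected", [
        (1, 1, 0.5, 2.0),
        (1, 0, 0.5, -2.0),
        (-1, 1, 0.25, -4.0),
    ])
    def test_substitution(self, y, a, pi, expected):
        mo = modified_outcome(np.array([y]), np.array([a]), np.array([pi]))
        assert mo.values[0] == pytest.approx(expected)

    def test_propensity_outside_open_interval_errors(self):
        with pytest.raises(ValueError, match="clip"):
            modified_outcome(np.array([1]), np.array([1]), np.array([1.0]))

    def test_unsigned_phenotype_rejected(self):
        with pytest.raises(ValueError, match="signed"):
            modified_outcome(np.array([0]), np.array([1]), np.array([0.5]))


class TestRobustModifiedOutcome:
    def test_constant_arm_share_propensity_reduces_to_plain(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, size=50)
        y = 2 * rng.integers(0, 2, size=50) - 1
        pi = np.full(50, a.mean())
        plain = modified_outcome(y, a, pi).values
        robust = robust_modified_outcome(y, a, pi).values
        np.testing.assert_allclose(robust, plain, rtol=1e-12)

    def test_normalized_weights_average_one(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, size=80)
        y = 2 * rng.integers(0, 2, size=80) - 1
        pi = rng.uniform(0.2, 0.8, size=80)
        w1 = (a / pi)
        w0 = ((1 - a) / (1 - pi))
        assert (w1 / w1.mean()).mean() == pytest.approx(1.0)
        assert (w0 / w0.mean()).mean() == pytest.approx(1.0)
        # and the outcome uses exactly those normalized weights
        vals = robust_modified_outcome(y, a, pi).values
        np.testing.assert_allclose(vals, y * (w1 / w1.mean() - w0 / w0.mean()))

    def test_hand_evaluated_toy(self):
        # n=4, pi=(0.2,0.8,0.5,0.5), a=(1,1,0,0), y all +1:
        # w1=(5,1.25,0,0), mean 1.5625 -> (3.2,0.8,0,0)
        # w0=(0,0,2,2), mean 1 -> (0,0,2,2)
        vals = robust_modified_outcome(
            np.ones(4), np.array([1, 1, 0, 0]),
            np.array([0.2, 0.8, 0.5, 0.5])).values
        np.testing.assert_allclose(vals, [3.2, 0.8, -2.0, -2.0], rtol=1e-12)

    def test_empty_arm_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            robust_modified_outcome(np.ones(3), np.ones(3),
                                    np.full(3, 0.5))


def test_modified_outcome_mean_recovers_twice_delta():
    """With known propensities, E[y_tilde | X stratum] = 2 delta(X)."""
    rng = np.random.default_rng(42)
    n = 5000
    x = rng.integers(0, 2, size=n)
    pi = np.where(x == 1, 0.6, 0.3)          # true P(a=1 | x)
    a = (rng.random(n) < pi).astype(int)
    # P(y=+1 | a, x): interaction in stratum x=1 only
    p_case = np.select(
        [(x == 1) & (a == 1), (x == 1) & (a == 0)], [0.8, 0.4], default=0.3)
    y = np.where(rng.random(n) < p_case, 1.0, -1.0)
    # delta(x) = (E[Y|A=1,x] - E[Y|A=0,x]) / 2 with E[Y|..] = 2p - 1
    delta = {1: ((2 * 0.8 - 1) - (2 * 0.4 - 1)) / 2, 0: 0.0}
    mo = modified_outcome(y, a, pi)
    for stratum in (0, 1):
        vals = mo.values[x == stratum]
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - 2 * delta[stratum]) < 3 * se + 1e-9


class TestFitInteractionScores:
    def test_pure_noise_with_penalty_floor_yields_all_zero_scores(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(300, 15)).astype(float)
        y = rng.normal(size=300)
        ts = fit_interaction_scores(X, y, seed=0, alphas=[0.3, 0.5, 1.0])
        assert (ts.scores == 0).all()

    def test_planted_signal_attains_max_score(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            X = rng.integers(0, 3, size=(500, 10)).astype(float)
            y = 2.0 * X[:, 4] + rng.normal(size=500)
            ts = fit_interaction_scores(X, y, seed=rep)
            hits += ts.scores.argmax() == 4
        assert hits == 10

    def test_matches_coordinate_descent_oracle(self):
        # independent from-scratch coordinate descent on the elastic-net
        # objective 1/(2n)||y - Xw||^2 + al*|w|_1 + a(1-l)/2*|w|^2
        rng = np.random.default_rng(7)
        n, p = 20, 3
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ np.array([1.0, -0.5, 0.0]) + rng.normal(scale=0.5, size=n)
        yc = y - y.mean()
        alpha, l1 = 0.1, 0.5

        w = np.zeros(p)
        for _ in range(5000):
            for j in range(p):
                r = yc - X @ w + X[:, j] * w[j]
                rho_j = X[:, j] @ r / n
                z = (X[:, j] ** 2).mean() + alpha * (1 - l1)
                w[j] = np.sign(rho_j) * max(abs(rho_j) - alpha * l1, 0) / z
        ts = fit_interaction_scores(X, y, l1_ratio=l1, n_folds=4, seed=0,
                                    alphas=[alpha])
        np.testing.assert_allclose(ts.scores, np.abs(w), atol=1e-6)

    def test_constant_column_dropped_with_zero_score(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4))
        X[:, 2] = 1.0
        y = rng.normal(size=100)
        ts = fit_interaction_scores(X, y, seed=1)
        assert ts.scores[2] == 0.0


class TestScoreAllTargets:
    def _setup(self, tiny_like, n=120, seed=0):
        rng = np.random.default_rng(seed)
        from epinet.gwas_io import GenotypeData, SnpMeta
        p = 4
        snps = [SnpMeta(f"rs{j}", "1", 100 * (j + 1)) for j in range(p)]
        matrix = rng.integers(0, 3, size=(n, p)).astype(np.int8)
        pheno = rng.integers(0, 2, size=n).astype(np.int8)
        pheno[0], pheno[1] = 0, 1
        gd = GenotypeData([f"s{i}" for i in range(n)], snps, matrix, pheno)
        model = fit_hmm(gd.imputed_matrix().astype(int), K=2, n_iter=4,
                        seed=0, chrom="1", n_restarts=1)
        return gd, {"1": model}

    def test_two_snp_map_shapes(self):
        gd, models = self._setup(None)
        smap = SnpGeneMap("physical", {"gA": frozenset({0}),
                                       "gB": frozenset({2})})
        sm = score_all_targets(gd, smap, models, ScoringConfig(seed=0))
        assert sm.p == 2
        assert np.isnan(sm.scores[0, 0]) and np.isnan(sm.scores[1, 1])
        assert np.isfinite(sm.scores[0, 1]) and np.isfinite(sm.scores[1, 0])

    def test_row_count_equals_mapped_snps(self):
        gd, models = self._setup(None)
        smap = SnpGeneMap("physical", {"gA": frozenset({0, 1}),
                                       "gB": frozenset({2, 3})})
        sm = score_all_targets(gd, smap, models, ScoringConfig(seed=0))
        assert sm.scores.shape == (4, 4)

    def test_degenerate_target_flagged(self):
        gd, models = self._setup(None)
        gd.matrix[:, 1] = 2  # dominant-binarized state constant
        model = fit_hmm(gd.imputed_matrix().astype(int), K=2, n_iter=3,
                        seed=0, chrom="1", n_restarts=1)
        smap = SnpGeneMap("physical", {"gA": frozenset({0, 1}),
                                       "gB": frozenset({2})})
        sm = score_all_targets(gd, smap, {"1": model}, ScoringConfig(seed=0))
        assert 1 in sm.degenerate
        row = sm.scores[1]
        assert np.nansum(row) == 0.0


def test_plain_and_robust_rankings_agree_under_constant_propensity():
    """Constant propensity: identical rankings at the empirical arm share
    (exact reduction); for other constants the support and the top candidate
    still agree (arm-wise rescaling preserves the dominant signal)."""
    rng = np.random.default_rng(9)
    n = 400
    X = rng.integers(0, 3, size=(n, 8)).astype(float)
    a = rng.integers(0, 2, size=n)
    y = np.where(rng.random(n) < 0.4 + 0.2 * a * (X[:, 3] > 0), 1.0, -1.0)

    pi_share = np.full(n, a.mean())
    ts_p = fit_interaction_scores(X, modified_outcome(y, a, pi_share), seed=2)
    ts_r = fit_interaction_scores(X, robust_modified_outcome(y, a, pi_share),
                                  seed=2)
    np.testing.assert_allclose(ts_p.scores, ts_r.scores, atol=1e-10)

    pi_off = np.full(n, 0.45)
    ts_p = fit_interaction_scores(X, modified_outcome(y, a, pi_off), seed=2)
    ts_r = fit_interaction_scores(X, robust_modified_outcome(y, a, pi_off),
                                  seed=2)
    assert (ts_p.scores > 0).tolist() == (ts_r.scores > 0).tolist()
    assert ts_p.scores.argmax() == ts_r.scores.argmax()
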