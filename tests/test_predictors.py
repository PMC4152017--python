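"""Predictors against dense nm x nm oracles, hand examples and invariants."""

import numpy as np
import pytest

import adrlink as al
from adrlink import PredictorConfig, SimilarityMatrix
from adrlink.predictors import (
    KernelMatrix,
    _irls_logistic,
    gwpm_predict,
    logistic_scores,
    make_kernel,
    nn_predict,
    pair_covariates,
    rls_predict,
    slp_predict,
)

from conftest import random_network, random_similarity


def vec(Z):
    """Column-major vec of the ADR-major matrix Z = Y.T (package convention)."""
    return Z.ravel(order="F")


def unvec(v, m, n):
    return v.reshape((m, n), order="F")


def make_instance(seed, n=None, m=None, psd=True):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(2, 6))
    m = m or int(rng.integers(2, 6))
    net = random_network(rng, n, m)
    Sd = random_similarity(rng, net.drug_ids, "drug")
    Sa = random_similarity(rng, net.adr_ids, "adr")
    if psd:
        Kd = make_kernel(Sd, "shift")
        Ka = make_kernel(Sa, "shift")
        return net, Sd, Sa, Kd, Ka
    return net, Sd, Sa, None, None


def dense_rls(Kd, Ka, Y, mode, sigma):
    """Explicit nm x nm Kronecker solve (the oracle)."""
    n, m = Y.shape
    if mode == "kp":
        K = np.kron(Kd, Ka)
    else:
        K = np.kron(Kd, np.eye(m)) + np.kron(np.eye(n), Ka)
    f = K @ np.linalg.solve(K + sigma * np.eye(n * m), vec(Y.T))
    return unvec(f, m, n).T


def dense_slp(Sd, Sa, Y, mode, beta):
    """Explicit pair-graph normalized-Laplacian solve (the oracle)."""
    n, m = Y.shape
    if mode == "kp":
        W = np.kron(Sd, Sa)
    else:
        W = np.kron(Sd, np.eye(m)) + np.kron(np.eye(n), Sa)
    d = W.sum(axis=1)
    dis = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = np.eye(n * m) - (dis[:, None] * W) * dis[None, :]
    dead = d == 0
    L[dead, :] = 0.0
    L[:, dead] = 0.0
    f = np.linalg.solve(np.eye(n * m) + beta * L, vec(Y.T))
    return unvec(f, m, n).T


class TestMakeKernel:
    def test_psd_input_unchanged(self):
        S = SimilarityMatrix("drug", "blended", ("a", "b"), np.array([[1.0, 0.2], [0.2, 1.0]]))
        K = make_kernel(S, "shift")
        np.testing.assert_array_equal(K.K, S.S)

    def test_shift_moves_diagonal(self):
        S = SimilarityMatrix("drug", "cn", ("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]))
        K = make_kernel(S, "shift")  # eigenvalues 3 and -1
        np.testing.assert_allclose(np.diag(K.K), 2.0 + 1e-8)
        assert np.linalg.eigvalsh(K.K)[0] >= -1e-8

    def test_clip_reconstruction(self):
        S = SimilarityMatrix("drug", "cn", ("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        K = make_kernel(S, "clip")  # keep only the +1 eigenpair
        np.testing.assert_allclose(K.K, [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)

    def test_off_mode_rejects_indefinite(self):
        S = SimilarityMatrix("drug", "cn", ("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="not PSD"):
            make_kernel(S, "off")


class TestRLS:
    def test_identity_kernels_halve_y(self, tiny_net):
        I_d = KernelMatrix("drug", "x", tiny_net.drug_ids, np.eye(2))
        I_a = KernelMatrix("adr", "x", tiny_net.adr_ids, np.eye(3))
        F = rls_predict(I_d, I_a, tiny_net, mode="avg", sigma=1.0)
        np.testing.assert_allclose(F.F, tiny_net.Y / 2.0)

    @pytest.mark.parametrize("mode", ["kp", "ks", "avg"])
    def test_sigma_to_zero_recovers_y(self, mode):
        net, Sd, Sa, Kd, Ka = make_instance(1, n=4, m=3)
        F = rls_predict(Kd, Ka, net, mode=mode, sigma=1e-12)
        np.testing.assert_allclose(F.F, net.Y, atol=1e-4)

    @pytest.mark.parametrize("mode", ["kp", "ks"])
    @pytest.mark.parametrize("seed", range(10))
    def test_factorized_solve_matches_dense_oracle(self, mode, seed):
        net, _, _, Kd, Ka = make_instance(seed)
        sigma = 0.7
        F = rls_predict(Kd, Ka, net, mode=mode, sigma=sigma)
        expected = dense_rls(Kd.K, Ka.K, net.Y, mode, sigma)
        np.testing.assert_allclose(F.F, expected, atol=1e-8)

    def test_sigma_must_be_positive(self):
        net, _, _, Kd, Ka = make_instance(2)
        with pytest.raises(ValueError, match="sigma"):
            rls_predict(Kd, Ka, net, sigma=0.0)


class TestSLP:
    @pytest.mark.parametrize("mode", ["kp", "ks", "avg"])
    def test_beta_zero_returns_y(self, mode):
        net, Sd, Sa, _, _ = make_instance(3, n=4, m=4)
        F = slp_predict(Sd, Sa, net, mode=mode, beta=0.0)
        np.testing.assert_allclose(F.F, net.Y, atol=1e-10)

    @pytest.mark.parametrize("mode", ["kp", "ks"])
    @pytest.mark.parametrize("seed", range(10))
    def test_pair_solve_matches_dense_oracle(self, mode, seed):
        net, Sd, Sa, _, _ = make_instance(seed + 100)
        beta = 1.3
        F = slp_predict(Sd, Sa, net, mode=mode, beta=beta)
        expected = dense_slp(Sd.S, Sa.S, net.Y, mode, beta)
        np.testing.assert_allclose(F.F, expected, atol=1e-8)

    def test_identity_similarities_pass_through(self, tiny_net):
        # S = I means the Laplacian of the similarity graph vanishes
        I_d = SimilarityMatrix("drug", "blended", tiny_net.drug_ids, np.eye(2))
        I_a = SimilarityMatrix("adr", "blended", tiny_net.adr_ids, np.eye(3))
        F = slp_predict(I_d, I_a, tiny_net, mode="avg", beta=5.0)
        np.testing.assert_allclose(F.F, tiny_net.Y)

    def test_negative_beta_rejected(self):
        net, Sd, Sa, _, _ = make_instance(4)
        with pytest.raises(ValueError, match="beta"):
            slp_predict(Sd, Sa, net, beta=-1.0)


class TestNN:
    def test_all_zero_network_scores_zero(self):
        net = al.BipartiteNetwork(("d1", "d2"), ("a1", "a2"), np.zeros((2, 2)))
        rng = np.random.default_rng(0)
        Sd = random_similarity(rng, net.drug_ids, "drug")
        Sa = random_similarity(rng, net.adr_ids, "adr")
        F = nn_predict(Sd, Sa, net)
        np.testing.assert_array_equal(F.F, np.zeros((2, 2)))

    def test_hand_example_half_times_similarity(self):
        # only drug-side evidence: Sd(d1,d2)=0.8 and Y(d2,e1)=1
        Y = np.array([[0.0], [1.0]])
        net = al.BipartiteNetwork(("d1", "d2"), ("e1",), Y)
        Sd = SimilarityMatrix("drug", "blended", net.drug_ids, np.array([[1.0, 0.8], [0.8, 1.0]]))
        Sa = SimilarityMatrix("adr", "blended", net.adr_ids, np.eye(1))
        F = nn_predict(Sd, Sa, net)
        assert F.F[0, 0] == pytest.approx(0.4)

    def test_bounded_by_max_offdiagonal_similarity(self):
        rng = np.random.default_rng(6)
        net = random_network(rng, 6, 5)
        Sd = random_similarity(rng, net.drug_ids, "drug")
        Sa = random_similarity(rng, net.adr_ids, "adr")
        F = nn_predict(Sd, Sa, net)
        cap = max(
            Sd.S[~np.eye(6, dtype=bool)].max(),
            Sa.S[~np.eye(5, dtype=bool)].max(),
        )
        assert F.F.max() <= cap + 1e-12


class TestGWPM:
    def test_side_endpoint_reduces_to_drug_profile(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, 5, 4)
        Sd = random_similarity(rng, net.drug_ids, "drug")
        Sa = random_similarity(rng, net.adr_ids, "adr")
        F1 = gwpm_predict(Sd, Sa, net, w_side=1.0)
        W = Sd.S.copy()
        np.fill_diagonal(W, 0.0)
        expected = (W / W.sum(axis=1, keepdims=True)) @ net.Y
        np.testing.assert_allclose(F1.F, expected)

    def test_all_ones_fixed_point(self):
        rng = np.random.default_rng(8)
        net = al.BipartiteNetwork(("x", "y", "z"), ("p", "q"), np.ones((3, 2)))
        Sd = random_similarity(rng, net.drug_ids, "drug")
        Sa = random_similarity(rng, net.adr_ids, "adr")
        F = gwpm_predict(Sd, Sa, net)
        np.testing.assert_allclose(F.F, np.ones((3, 2)))

    def test_hand_weighted_average(self):
        # WPd(d1,e1) = 0.6*1 / (0.6+0.2) = 0.75
        Y = np.array([[0.0], [1.0], [0.0]])
        net = al.BipartiteNetwork(("d1", "d2", "d3"), ("e1",), Y)
        S = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.0], [0.2, 0.0, 1.0]])
        Sd = SimilarityMatrix("drug", "blended", net.drug_ids, S)
        Sa = SimilarityMatrix("adr", "blended", net.adr_ids, np.eye(1))
        F = gwpm_predict(Sd, Sa, net, w_side=1.0)
        assert F.F[0, 0] == pytest.approx(0.75)

    def test_scores_in_unit_interval_and_monotone(self):
        rng = np.random.default_rng(9)
        net = random_network(rng, 6, 6)
        Sd = random_similarity(rng, net.drug_ids, "drug")
        Sa = random_similarity(rng, net.adr_ids, "adr")
        F = gwpm_predict(Sd, Sa, net)
        assert F.F.min() >= 0.0 and F.F.max() <= 1.0
        zeros = np.argwhere(net.Y == 0)
        i, j = zeros[0]
        Y2 = net.Y.copy()
        Y2[i, j] = 1.0
        F2 = gwpm_predict(Sd, Sa, net.with_matrix(Y2))
        assert (F2.F >= F.F - 1e-12).all()


class TestUnifiedLinearForm:
    """Every kernel/propagation/profile predictor is linear in Y."""

    @pytest.mark.parametrize(
        "config",
        [
            PredictorConfig(algorithm="rls", mode="kp"),
            PredictorConfig(algorithm="rls", mode="ks"),
            PredictorConfig(algorithm="rls", mode="avg"),
            PredictorConfig(algorithm="slp", mode="kp", beta=0.8),
            PredictorConfig(algorithm="slp", mode="ks", beta=0.8),
            PredictorConfig(algorithm="slp", mode="avg", beta=0.8),
            PredictorConfig(algorithm="gwpm", w_side=0.3),
        ],
        ids=lambda c: f"{c.algorithm}-{c.mode}",
    )
    def test_additivity_in_y(self, config):
        rng = np.random.default_rng(10)
        n, m = 4, 5
        ids_d = tuple(f"d{i}" for i in range(n))
        ids_a = tuple(f"a{j}" for j in range(m))
        Sd = random_similarity(rng, ids_d, "drug")
        Sa = random_similarity(rng, ids_a, "adr")
        Y1 = (rng.random((n, m)) < 0.4).astype(float)
        Y2 = ((rng.random((n, m)) < 0.4) & (Y1 == 0)).astype(float)
        nets = [al.BipartiteNetwork(ids_d, ids_a, Y) for Y in (Y1, Y2, Y1 + Y2)]
        # the similarity operator must stay fixed: similarities are supplied,
        # not recomputed from Y
        F1, F2, F12 = (al.predict(Sd, Sa, net, config).F for net in nets)
        np.testing.assert_allclose(F12, F1 + F2, atol=1e-8)

    @pytest.mark.parametrize(
        "config",
        [
            PredictorConfig(algorithm="rls", mode="ks"),
            PredictorConfig(algorithm="slp", mode="kp", beta=1.0),
            PredictorConfig(algorithm="gwpm"),
            PredictorConfig(algorithm="nn"),
        ],
        ids=lambda c: c.algorithm + "-" + c.mode,
    )
    def test_permutation_equivariance(self, config):
        rng = np.random.default_rng(11)
        net, Sd, Sa, _, _ = make_instance(12, n=5, m=4)
        F = al.predict(Sd, Sa, net, config).F
        pd = rng.permutation(5)
        pa = rng.permutation(4)
        net_p = al.BipartiteNetwork(
            tuple(net.drug_ids[i] for i in pd),
            tuple(net.adr_ids[j] for j in pa),
            net.Y[np.ix_(pd, pa)],
        )
        Sd_p = SimilarityMatrix("drug", Sd.source, net_p.drug_ids, Sd.S[np.ix_(pd, pd)])
        Sa_p = SimilarityMatrix("adr", Sa.source, net_p.adr_ids, Sa.S[np.ix_(pa, pa)])
        F_p = al.predict(Sd_p, Sa_p, net_p, config).F
        np.testing.assert_allclose(F_p, F[np.ix_(pd, pa)], atol=1e-8)


class TestLogisticBaseline:
    def test_separating_covariate_preserves_ranking(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(40)
        y = (x > 0).astype(float)
        X = x[:, None]
        x_test = rng.standard_normal(15)
        scores = logistic_scores(X, y, x_test[:, None])
        # a monotone link preserves the covariate's ordering (saturated
        # probabilities may tie at the extremes)
        assert (np.diff(scores[np.argsort(x_test)]) >= -1e-12).all()
        assert scores[np.argmax(x_test)] > scores[np.argmin(x_test)]

    def test_constant_covariates_give_prevalence(self):
        X = np.ones((20, 2))
        y = np.array([1.0] * 6 + [0.0] * 14)
        scores = logistic_scores(X, y, np.ones((5, 2)))
        np.testing.assert_allclose(scores, 0.3, atol=1e-6)

    def test_coefficients_match_independent_irls(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((60, 2))
        logit = 0.5 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
        y = (rng.random(60) < 1 / (1 + np.exp(-logit))).astype(float)
        import statsmodels.api as sm

        res = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        ours = _irls_logistic(sm.add_constant(X), y, ridge=0.0)
        np.testing.assert_allclose(ours, res.params, atol=1e-6)

    def test_pair_covariate_table_shape(self, tiny_net):
        rng = np.random.default_rng(15)
        Sd = random_similarity(rng, tiny_net.drug_ids, "drug")
        Sa = random_similarity(rng, tiny_net.adr_ids, "adr")
        X = pair_covariates(tiny_net, [Sd], [Sa])
        assert X.shape == (6, 4)  # WPd, WPa, drug degree, adr degree
        np.testing.assert_array_equal(X[:, 2], np.repeat(tiny_net.drug_degrees(), 3))
        np.testing.assert_array_equal(X[:, 3], np.tile(tiny_net.adr_degrees(), 2))
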