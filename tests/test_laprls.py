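"""LapRLS core: Laplacian normalization, closed-form classifier, fusion."""

import math

import numpy as np
import pytest
import scipy.optimize

from laplink import network_from_pairs
from laplink.laprls import (
    ModelParams,
    ScoreMatrix,
    UnknownDiseaseError,
    combine,
    normalized_laplacian,
    optimal_classifier,
    predict,
    rank_candidates,
)


def random_pd_kernel(rng, n):
    """Gaussian kernel of distinct random points: strictly positive definite."""
    X = rng.normal(size=(n, 3))
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    return np.exp(-0.5 * d2)


class TestNormalizedLaplacian:
    def test_all_ones_kernel(self):
        L = normalized_laplacian(np.ones((2, 2)))
        assert np.allclose(L, [[0.5, -0.5], [-0.5, 0.5]])

    def test_identity_kernel_gives_zero(self):
        assert np.allclose(normalized_laplacian(np.eye(4)), 0.0)

    def test_two_point_gaussian_kernel(self):
        a = math.exp(-2)
        L = normalized_laplacian(np.array([[1.0, a], [a, 1.0]]))
        expected = a / (1 + a)  # 0.119203...
        assert L[0, 0] == pytest.approx(expected, abs=1e-9)
        assert L[0, 1] == pytest.approx(-expected, abs=1e-9)
        assert expected == pytest.approx(0.119203, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_spectrum_and_sqrt_degree_null_vector(self, seed):
        rng = np.random.default_rng(seed)
        K = random_pd_kernel(rng, 6)
        L = normalized_laplacian(K)
        ev = np.linalg.eigvalsh(L)
        assert ev.min() >= -1e-10
        assert ev.max() <= 2 + 1e-10
        v = np.sqrt(K.sum(axis=1))
        assert np.linalg.norm(L @ v) <= 1e-8 * np.linalg.norm(v)

    def test_asymmetric_kernel_rejected(self):
        with pytest.raises(ValueError):
            normalized_laplacian(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestOptimalClassifier:
    def test_eta_zero_returns_labels_exactly(self, rng):
        K = random_pd_kernel(rng, 5)
        L = normalized_laplacian(K)
        A = rng.integers(0, 2, size=(5, 3)).astype(float)
        assert np.array_equal(optimal_classifier(K, L, A, eta=0.0), A)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_unreduced_closed_form(self, seed):
        # K (K + eta L K)^(-1) A computed independently with an explicit inverse
        rng = np.random.default_rng(seed)
        K = random_pd_kernel(rng, 5)
        L = normalized_laplacian(K)
        A = rng.integers(0, 2, size=(5, 2)).astype(float)
        eta = rng.uniform(0.1, 3.0)
        expected = K @ np.linalg.inv(K + eta * L @ K) @ A
        assert np.allclose(optimal_classifier(K, L, A, eta), expected, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_minimizes_trace_form_cost(self, seed):
        # numeric-optimizer oracle for min ||A - F||^2 + eta tr(F^T L F)
        rng = np.random.default_rng(seed)
        n, m, eta = 4, 2, 1.0
        K = random_pd_kernel(rng, n)
        L = normalized_laplacian(K)
        A = rng.integers(0, 2, size=(n, m)).astype(float)

        def cost(flat):
            F = flat.reshape(n, m)
            return ((A - F) ** 2).sum() + eta * np.trace(F.T @ L @ F)

        def grad(flat):
            F = flat.reshape(n, m)
            return (2 * (F - A) + 2 * eta * (L @ F)).ravel()

        res = scipy.optimize.minimize(
            cost, np.zeros(n * m), jac=grad, method="BFGS", tol=1e-14
        )
        F_hat = optimal_classifier(K, L, A, eta)
        assert np.allclose(F_hat, res.x.reshape(n, m), atol=1e-6)
        assert cost(F_hat.ravel()) <= res.fun + 1e-10

    def test_large_eta_flattens_to_laplacian_null_space(self, rng):
        K = random_pd_kernel(rng, 5)
        L = normalized_laplacian(K)
        A = rng.integers(0, 2, size=(5, 2)).astype(float)
        F = optimal_classifier(K, L, A, eta=1e9)
        v = np.sqrt(K.sum(axis=1))
        proj = np.outer(v, v) @ A / (v @ v)
        assert np.allclose(F, proj, atol=1e-6)


class TestCombine:
    def test_mean_of_identical_parts(self, rng):
        Y = rng.integers(0, 2, size=(3, 2)).astype(float)
        assert np.allclose(combine(Y, Y.T, lw=0.5), Y)

    def test_convexity_endpoints(self, rng):
        FM = rng.normal(size=(3, 2))
        FD = rng.normal(size=(2, 3))
        assert np.allclose(combine(FM, FD, lw=1.0), FM)
        assert np.allclose(combine(FM, FD, lw=0.0), FD.T)

    def test_incompatible_shapes_rejected(self):
        with pytest.raises(ValueError):
            combine(np.zeros((3, 2)), np.zeros((3, 2)))


def straight_line_pipeline(Y, eta_m=1.0, eta_d=1.0, lw=0.5):
    """Independent end-to-end evaluation of the score matrix: bandwidths,
    kernels, Laplacians, the *unreduced* closed forms via explicit inverses,
    and the weighted fusion -- no shared code with the implementation."""
    Y = np.asarray(Y, dtype=float)
    nm, nd = Y.shape
    gm = 1.0 / (np.sum(Y**2) / nm)
    gd = 1.0 / (np.sum(Y**2) / nd)
    SM = np.array(
        [[math.exp(-gm * np.sum((Y[i] - Y[j]) ** 2)) for j in range(nm)] for i in range(nm)]
    )
    SD = np.array(
        [
            [math.exp(-gd * np.sum((Y[:, i] - Y[:, j]) ** 2)) for j in range(nd)]
            for i in range(nd)
        ]
    )

    def lap(S):
        D = np.diag(S.sum(axis=1))
        Dm = np.diag(1 / np.sqrt(np.diag(D)))
        return Dm @ (D - S) @ Dm

    LM, LD = lap(SM), lap(SD)
    A = Y.T
    FM = SM @ np.linalg.inv(SM + eta_m * LM @ SM) @ A.T
    FD = SD @ np.linalg.inv(SD + eta_d * LD @ SD) @ A
    return lw * FM + (1 - lw) * FD.T


class TestPredict:
    def test_matches_independent_straight_line_run(self, diag_net):
        F = predict(diag_net).values
        assert np.allclose(F, straight_line_pipeline(diag_net.Y), atol=1e-10)
        # known pairs outscore unknown pairs
        assert F[0, 0] > F[0, 1] and F[1, 1] > F[1, 0]

    def test_eta_zero_recovers_adjacency(self, diag_net):
        params = ModelParams(eta_m=0.0, eta_d=0.0, lw=0.5)
        assert np.array_equal(predict(diag_net, params).values, diag_net.Y)

    def test_straight_line_agreement_on_larger_network(self):
        net = network_from_pairs(
            [("m1", "d1"), ("m2", "d1"), ("m2", "d2"), ("m3", "d3"), ("m1", "d3")]
        )
        F = predict(net, ModelParams(eta_m=0.7, eta_d=1.3, lw=0.3)).values
        expected = straight_line_pipeline(net.Y, eta_m=0.7, eta_d=1.3, lw=0.3)
        assert np.allclose(F, expected, atol=1e-10)

    def test_permutation_equivariance(self, rng, structured_net):
        F = predict(structured_net).values
        rp = rng.permutation(structured_net.nm)
        cp = rng.permutation(structured_net.nd)
        from laplink.associations import AdjacencyNetwork

        permuted = AdjacencyNetwork(
            structured_net.Y[np.ix_(rp, cp)],
            [structured_net.microbe_index[i] for i in rp],
            [structured_net.disease_index[j] for j in cp],
        )
        Fp = predict(permuted).values
        assert np.allclose(Fp, F[np.ix_(rp, cp)], atol=1e-10)

    def test_duplicate_input_rows_do_not_change_scores(self):
        pairs = [("m1", "d1"), ("m2", "d1"), ("m2", "d2")]
        F1 = predict(network_from_pairs(pairs)).values
        F2 = predict(network_from_pairs(pairs + pairs)).values
        assert np.array_equal(F1, F2)


class TestRankCandidates:
    def _scores(self, col, ycol):
        net_Y = np.array(ycol, dtype=np.int8).reshape(-1, 1)
        from laplink.associations import AdjacencyNetwork

        names = [f"m{i+1}" for i in range(len(col))]
        net = AdjacencyNetwork(net_Y, names, ["dz"])
        sm = ScoreMatrix(np.array(col, dtype=float).reshape(-1, 1), names, ["dz"])
        return sm, net

    def test_known_pairs_excluded_and_sorted(self):
        sm, net = self._scores([0.9, 0.1, 0.5], [0, 1, 0])
        assert rank_candidates(sm, net, "dz", top_k=2) == [("m1", 0.9), ("m3", 0.5)]

    def test_top_k_clamped_to_candidates(self):
        sm, net = self._scores([0.9, 0.1, 0.5], [0, 1, 0])
        assert len(rank_candidates(sm, net, "dz", top_k=10)) == 2

    def test_ties_broken_by_index_order(self):
        sm, net = self._scores([0.5, 0.5, 0.5], [0, 0, 0])
        assert [m for m, _ in rank_candidates(sm, net, "dz")] == ["m1", "m2", "m3"]

    def test_unknown_disease_lists_near_matches(self):
        sm, net = self._scores([0.9], [0])
        with pytest.raises(UnknownDiseaseError) as exc:
            rank_candidates(sm, net, "dzz")
        assert "dz" in str(exc.value)
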