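"""Logistic matrix factorization: Laplacians, objective, gradients, fit."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from mirdfuse.nrlmf import (
    NRLMF,
    LogisticFactors,
    NrlmfParams,
    build_knn_laplacian,
    fit_nrlmf,
    nrlmf_gradients,
    nrlmf_objective,
    predict_nrlmf,
)


def brute_objective(U, V, Y, Ld, Lt, params):
    """Naive double-loop evaluation of the NRLMF loss."""
    c = params.c
    total = 0.0
    for i in range(Y.shape[0]):
        for j in range(Y.shape[1]):
            x = float(U[i] @ V[j])
            y = Y[i, j]
            total += (1 + c * y - y) * np.log1p(np.exp(x)) - c * y * x
    Rd = params.lambda_d * np.eye(U.shape[0]) + params.alpha * Ld
    Rt = params.lambda_t * np.eye(V.shape[0]) + params.beta * Lt
    total += 0.5 * np.trace(U.T @ Rd @ U) + 0.5 * np.trace(V.T @ Rt @ V)
    return total


def random_problem(rng, m=4, n=3, r=2):
    Y = (rng.random((m, n)) < 0.4).astype(float)
    U = rng.normal(size=(m, r))
    V = rng.normal(size=(n, r))
    Sd = rng.random((m, m))
    Sd = (Sd + Sd.T) / 2
    np.fill_diagonal(Sd, 1)
    Sm = rng.random((n, n))
    Sm = (Sm + Sm.T) / 2
    np.fill_diagonal(Sm, 1)
    Ld = build_knn_laplacian(Sd, min(2, m - 1)).L
    Lt = build_knn_laplacian(Sm, min(2, n - 1)).L
    return U, V, Y, Ld, Lt


class TestKnnLaplacian:
    def test_identity_similarity_gives_zero_laplacian(self):
        lap = build_knn_laplacian(np.eye(4), 2)
        np.testing.assert_array_equal(lap.W_knn, np.zeros((4, 4)))
        np.testing.assert_array_equal(lap.L, np.zeros((4, 4)))

    def test_dominant_pair_hand_laplacian(self):
        # nodes 0-1 strongly similar (0.8); with k=1 rows 0 and 1 pick each
        # other and row 2 picks node 1 (0.2).  Symmetrizing halves the
        # single-sided 2-1 edge.
        S = np.array([[1.0, 0.8, 0.1], [0.8, 1.0, 0.2], [0.1, 0.2, 1.0]])
        lap = build_knn_laplacian(S, 1)
        W_expected = np.array([[0.0, 0.8, 0.0], [0.8, 0.0, 0.1], [0.0, 0.1, 0.0]])
        np.testing.assert_allclose(lap.W_knn, W_expected)
        np.testing.assert_allclose(lap.L, np.diag(W_expected.sum(1)) - W_expected)

    def test_psd_on_random_vectors(self, rng):
        S = rng.random((6, 6))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1)
        L = build_knn_laplacian(S, 3).L
        for _ in range(100):
            x = rng.normal(size=6)
            assert x @ L @ x >= -1e-10


class TestObjective:
    def test_closed_form_at_origin(self, rng):
        _, _, Y, Ld, Lt = random_problem(rng)
        params = NrlmfParams(rank=2, c=5)
        U = np.zeros((Y.shape[0], 2))
        V = np.zeros((Y.shape[1], 2))
        expected = np.log(2) * np.sum(1 + params.c * Y - Y)
        assert nrlmf_objective(U, V, Y, 0 * Ld, 0 * Lt, params) == pytest.approx(expected)

    def test_c1_no_positives_collapses_to_softplus(self, rng):
        U = rng.normal(size=(3, 2))
        V = rng.normal(size=(4, 2))
        Y = np.zeros((3, 4))
        params = NrlmfParams(rank=2, c=1, lambda_d=1e-12, lambda_t=1e-12, alpha=0, beta=0)
        X = U @ V.T
        expected = np.sum(np.log1p(np.exp(X)))
        assert nrlmf_objective(U, V, Y, np.zeros((3, 3)), np.zeros((4, 4)), params) == (
            pytest.approx(expected, rel=1e-10)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_sum(self, seed):
        rng = np.random.default_rng(seed)
        U, V, Y, Ld, Lt = random_problem(rng)
        params = NrlmfParams(rank=2, c=3, lambda_d=0.4, lambda_t=0.7, alpha=0.2, beta=0.3)
        fast = nrlmf_objective(U, V, Y, Ld, Lt, params)
        slow = brute_objective(U, V, Y, Ld, Lt, params)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_rotation_invariance_without_laplacians(self, rng):
        U, V, Y, Ld, Lt = random_problem(rng)
        params = NrlmfParams(rank=2, c=2, alpha=0, beta=0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        before = nrlmf_objective(U, V, Y, Ld, Lt, params)
        after = nrlmf_objective(U @ R, V @ R, Y, Ld, Lt, params)
        assert after == pytest.approx(before, rel=1e-10)

    def test_no_overflow_for_large_inner_products(self):
        U = np.full((2, 1), 500.0)
        V = np.full((3, 1), 500.0)
        params = NrlmfParams(rank=1)
        obj = nrlmf_objective(U, V, np.zeros((2, 3)), np.zeros((2, 2)), np.zeros((3, 3)), params)
        assert np.isfinite(obj)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        U, V, Y, Ld, Lt = random_problem(rng)
        params = NrlmfParams(rank=2, c=4, lambda_d=0.5, lambda_t=0.5, alpha=0.3, beta=0.2)
        gu, gv = nrlmf_gradients(U, V, Y, Ld, Lt, params)
        h = 1e-6
        for X, G in ((U, gu), (V, gv)):
            num = np.zeros_like(X)
            for idx in np.ndindex(X.shape):
                X[idx] += h
                up = nrlmf_objective(U, V, Y, Ld, Lt, params)
                X[idx] -= 2 * h
                dn = nrlmf_objective(U, V, Y, Ld, Lt, params)
                X[idx] += h
                num[idx] = (up - dn) / (2 * h)
            scale = max(np.abs(num).max(), 1.0)
            assert np.abs(G - num).max() / scale < 1e-5

    def test_zero_factors_zero_labels_zero_gradient(self):
        params = NrlmfParams(rank=2, c=5, alpha=0, beta=0)
        U = np.zeros((3, 2))
        V = np.zeros((4, 2))
        gu, gv = nrlmf_gradients(U, V, np.zeros((3, 4)), np.zeros((3, 3)), np.zeros((4, 4)), params)
        np.testing.assert_array_equal(gu, 0)
        np.testing.assert_array_equal(gv, 0)

    def test_gradient_vanishes_at_scalar_optimum(self):
        """On a 1x1 problem the analytic gradient must vanish where a direct
        numerical minimization of the objective lands."""
        Y = np.array([[1.0]])
        Z = np.zeros((1, 1))
        params = NrlmfParams(rank=1, c=2, lambda_d=0.5, lambda_t=0.5, alpha=0, beta=0)

        def f(x):
            return nrlmf_objective(x[:1].reshape(1, 1), x[1:].reshape(1, 1), Y, Z, Z, params)

        opt = minimize(f, x0=np.array([0.5, 0.5]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        U = opt.x[:1].reshape(1, 1)
        V = opt.x[1:].reshape(1, 1)
        gu, gv = nrlmf_gradients(U, V, Y, Z, Z, params)
        assert abs(gu[0, 0]) < 1e-4 and abs(gv[0, 0]) < 1e-4


class TestFit:
    def test_objective_decreases_and_deterministic(self, rng):
        Y = (rng.random((10, 8)) < 0.3).astype(float)
        Sd = np.eye(10)
        Sm = np.eye(8)
        params = NrlmfParams(rank=3, k_nn=2, max_iter=60, seed=7)
        f1, trace = fit_nrlmf(Y, Sd, Sm, params)
        assert trace[-1] <= trace[0]
        assert min(trace) == nrlmf_objective(
            f1.U, f1.V, Y, build_knn_laplacian(Sd, 2).L, build_knn_laplacian(Sm, 2).L, params
        )
        f2, _ = fit_nrlmf(Y, Sd, Sm, params)
        np.testing.assert_array_equal(f1.U, f2.U)

    def test_recovers_planted_structure(self):
        from mirdfuse import SyntheticSpec, generate_dataset
        from mirdfuse.evaluation import auc_score, make_folds

        Y, Sd, Sm, _ = generate_dataset(SyntheticSpec(p=40, q=40, rank=3, density=0.12, seed=3))
        fold = make_folds(Y.Y, 5, seed=3)[0]
        Y_train = np.zeros_like(Y.Y)
        Y_train[fold.train_pos[:, 0], fold.train_pos[:, 1]] = 1
        params = NrlmfParams(rank=5, max_iter=300, learn_rate=0.5, alpha=0.5, beta=0.5, seed=3)
        factors, _ = fit_nrlmf(Y_train, Sd.M, Sm.M, params)
        P = predict_nrlmf(factors)
        neg = Y.Y == 0
        scores = np.concatenate([P[fold.test_pos[:, 0], fold.test_pos[:, 1]], P[neg]])
        labels = np.concatenate([np.ones(len(fold.test_pos)), np.zeros(int(neg.sum()))])
        assert auc_score(scores, labels) > 0.9


class TestPredict:
    def test_zero_factors_give_half(self):
        P = predict_nrlmf(LogisticFactors(np.zeros((2, 3)), np.zeros((4, 3))))
        np.testing.assert_array_equal(P, np.full((2, 4), 0.5))

    def test_large_inner_product_saturates(self):
        P = predict_nrlmf(LogisticFactors(np.array([[50.0]]), np.array([[50.0]])))
        assert P[0, 0] == pytest.approx(1.0)

    def test_matches_logistic_formula(self, rng):
        U = rng.normal(size=(3, 2))
        V = rng.normal(size=(5, 2))
        P = predict_nrlmf(LogisticFactors(U, V))
        np.testing.assert_allclose(P, 1.0 / (1.0 + np.exp(-(U @ V.T))))
        assert ((P > 0) & (P < 1)).all()


def test_model_results_wrapper(small_dataset):
    Y, Sd, Sm, _ = small_dataset
    res = NRLMF(Y, Sm, Sd, NrlmfParams(rank=3, max_iter=20)).fit()
    assert res.predict().shape == Y.shape
    assert "rank 3" in res.summary()
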