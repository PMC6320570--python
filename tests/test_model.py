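"""Factorization core: SVD init, objective, ALS updates, fit and baseline."""

import math

import numpy as np
import pytest

from ddicmf import (
    FactorPair,
    HyperParams,
    SolverError,
    ValidationError,
    default_latent_dim,
    fit,
    fit_cmf,
    gip_kernel,
    l21_norm,
    objective,
    predict_scores,
    svd_init,
    update_A,
    update_B,
)
from ddicmf.datasets import InteractionMatrix


def _kernels_for(Y):
    im = InteractionMatrix(
        [f"d{i}" for i in range(Y.shape[0])],
        [f"s{j}" for j in range(Y.shape[1])],
        Y,
    )
    return gip_kernel(im, "drug").S, gip_kernel(im, "disease").S


def _random_problem(seed=0, n=20, m=15, density=0.25):
    rng = np.random.default_rng(seed)
    Y = (rng.random((n, m)) < density).astype(float)
    Y[0, 0] = Y[1, 1] = 1.0
    KD, Kd = _kernels_for(Y)
    return Y, KD, Kd


class TestSvdInit:
    def test_full_rank_reconstruction_is_exact(self):
        rng = np.random.default_rng(1)
        Y = rng.random((7, 5))
        fp = svd_init(Y, k=5)
        assert np.linalg.norm(Y - fp.A @ fp.B.T) < 1e-8

    def test_rank_one_outer_product(self):
        u, v = np.array([1.0, 2.0, 3.0]), np.array([2.0, 0.5])
        Y = np.outer(u, v)
        fp = svd_init(Y, k=1)
        np.testing.assert_allclose(fp.A @ fp.B.T, Y, atol=1e-8)

    def test_reconstruction_error_non_increasing_in_k(self):
        rng = np.random.default_rng(2)
        Y = rng.random((10, 8))
        errors = [
            np.linalg.norm(Y - (fp := svd_init(Y, k)).A @ fp.B.T) for k in range(1, 9)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_k_out_of_range(self):
        with pytest.raises(ValidationError):
            svd_init(np.eye(4), k=5)

    def test_default_latent_dim_rule(self):
        assert default_latent_dim(60, 40) == 40
        assert default_latent_dim(593, 313) == 50
        assert default_latent_dim(6, 4) == 4


class TestL21Norm:
    def test_three_four_five_rows(self):
        assert l21_norm(np.array([[3.0, 4.0], [0.0, 0.0]])) == pytest.approx(5.0)

    def test_zero_matrix(self):
        assert l21_norm(np.zeros((4, 3))) == 0.0

    def test_matches_elementwise_summation(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(5, 3))
        brute = sum(math.sqrt(sum(B[i, j] ** 2 for j in range(3))) for i in range(5))
        assert l21_norm(B) == pytest.approx(brute, abs=1e-12)


def _objective_by_loops(Y, A, B, KD, Kd, hp, include_l21=True):
    """Term-by-term re-evaluation with explicit loops (independent oracle)."""
    n, m = Y.shape
    k = A.shape[1]
    recon = sum(
        (Y[i, j] - sum(A[i, t] * B[j, t] for t in range(k))) ** 2
        for i in range(n) for j in range(m)
    )
    tik = hp.lambda_l * (np.sum(A**2) + np.sum(B**2))
    l21 = hp.lambda_l * sum(math.sqrt(np.sum(B[i] ** 2)) for i in range(m)) if include_l21 else 0.0
    net_d = hp.lambda_d * sum(
        (KD[i, j] - sum(A[i, t] * A[j, t] for t in range(k))) ** 2
        for i in range(n) for j in range(n)
    )
    net_t = hp.lambda_t * sum(
        (Kd[i, j] - sum(B[i, t] * B[j, t] for t in range(k))) ** 2
        for i in range(m) for j in range(m)
    )
    return recon + tik + l21 + net_d + net_t


class TestObjective:
    def test_zero_factors_closed_form(self):
        Y, KD, Kd = _random_problem(4, n=6, m=4)
        hp = HyperParams(lambda_l=0.5, lambda_d=0.2, lambda_t=0.3, k=2)
        fp = FactorPair(np.zeros((6, 2)), np.zeros((4, 2)))
        expected = (
            np.linalg.norm(Y) ** 2
            + 0.2 * np.linalg.norm(KD) ** 2
            + 0.3 * np.linalg.norm(Kd) ** 2
        )
        assert objective(Y, fp, KD, Kd, hp) == pytest.approx(expected, rel=1e-12)

    def test_exact_factorization_and_zero_penalties(self):
        rng = np.random.default_rng(5)
        A = np.abs(rng.normal(size=(6, 3)))
        B = np.abs(rng.normal(size=(4, 3)))
        M = A @ B.T
        Y = M / M.max()  # exactly rank 3, entries in [0, 1]
        fpk = svd_init(Y, 3)
        hp = HyperParams(lambda_l=0.0, lambda_d=0.0, lambda_t=0.0, k=3)
        val = objective(Y, fpk, np.eye(6), np.eye(4), hp)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self):
        Y, KD, Kd = _random_problem(6, n=6, m=4)
        rng = np.random.default_rng(7)
        fp = FactorPair(rng.normal(size=(6, 2)), rng.normal(size=(4, 2)))
        hp = HyperParams(lambda_l=0.7, lambda_d=0.05, lambda_t=0.03, k=2)
        expected = _objective_by_loops(Y, fp.A, fp.B, KD, Kd, hp)
        assert objective(Y, fp, KD, Kd, hp) == pytest.approx(expected, abs=1e-10)


class TestUpdates:
    def test_update_A_reduces_to_ridge(self):
        """With lambda_d=0 the A step is the closed-form ridge solution."""
        Y, KD, Kd = _random_problem(8, n=10, m=7)
        fp = svd_init(Y, 3)
        hp = HyperParams(lambda_l=0.8, lambda_d=0.0, lambda_t=0.0, k=3)
        A_new = update_A(Y, fp, KD, hp)
        ridge = Y @ fp.B @ np.linalg.inv(fp.B.T @ fp.B + 0.8 * np.eye(3))
        np.testing.assert_allclose(A_new, ridge, atol=1e-8)
        assert A_new.shape == (10, 3)

    def test_update_B_reduces_to_ridge(self):
        """With lambda_t=0 and the L2,1 weight off, the B step is plain ridge."""
        Y, KD, Kd = _random_problem(9, n=10, m=7)
        fp = svd_init(Y, 3)
        hp = HyperParams(lambda_l=0.8, lambda_d=0.0, lambda_t=0.0, k=3)
        B_new = update_B(Y, fp, Kd, hp, use_l21=False)
        ridge = Y.T @ fp.A @ np.linalg.inv(fp.A.T @ fp.A + 0.8 * np.eye(3))
        np.testing.assert_allclose(B_new, ridge, atol=1e-8)

    def test_duplicate_diseases_get_equal_rows(self):
        rng = np.random.default_rng(10)
        Y = (rng.random((8, 5)) < 0.4).astype(float)
        Y[:, 1] = Y[:, 0]  # two diseases with identical profiles
        Y[0, 0] = Y[0, 1] = 1.0
        _, Kd = _kernels_for(Y)
        fp = svd_init(Y, 3)
        B_new = update_B(Y, fp, Kd, HyperParams(lambda_l=0.5, k=3))
        np.testing.assert_allclose(B_new[0], B_new[1], atol=1e-10)

    def test_larger_lambda_l_shrinks_l21_after_one_update(self):
        Y, KD, Kd = _random_problem(11, n=12, m=9)
        fp = svd_init(Y, 4)
        norms = [
            l21_norm(update_B(Y, fp, Kd, HyperParams(lambda_l=ll, lambda_t=1e-3, k=4)))
            for ll in (0.25, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_singular_system_advises_regularization(self):
        Y = np.zeros((6, 4))
        Y[0, 0] = 1.0
        fp = FactorPair(np.zeros((6, 2)), np.zeros((4, 2)))
        hp = HyperParams(lambda_l=0.0, lambda_d=0.0, lambda_t=0.0, k=2)
        with pytest.raises(SolverError, match="lambda_l"):
            update_A(Y, fp, np.eye(6), hp)


class TestFit:
    def test_huge_tol_stops_after_one_iteration(self):
        Y, KD, Kd = _random_problem(12)
        res = fit(Y, KD, Kd, HyperParams(k=4, tol=1e12))
        assert res.iterations == 1
        assert len(res.objective_trace) == res.iterations + 1

    def test_trace_non_increasing_with_default_lambdas(self):
        Y, KD, Kd = _random_problem(0, n=20, m=15)
        res = fit(Y, KD, Kd, HyperParams(k=5))
        trace = np.asarray(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))
        assert trace[-1] <= trace[0]

    def test_final_objective_below_svd_init(self):
        Y, KD, Kd = _random_problem(13)
        hp = HyperParams(k=4)
        res = fit(Y, KD, Kd, hp)
        init_val = objective(Y, svd_init(Y, 4), KD, Kd, hp)
        assert res.objective_trace[-1] <= init_val

    def test_permutation_equivariance(self):
        Y, KD, Kd = _random_problem(14, n=12, m=9)
        hp = HyperParams(k=4, max_iter=60)
        res = fit(Y, KD, Kd, hp)
        rng = np.random.default_rng(15)
        perm = rng.permutation(12)
        res_p = fit(Y[perm], KD[np.ix_(perm, perm)], Kd, hp)
        np.testing.assert_allclose(res_p.factors.A, res.factors.A[perm], atol=1e-8)
        assert res_p.objective_trace[-1] == pytest.approx(res.objective_trace[-1], rel=1e-10)


class TestFitCmf:
    def test_matches_alternating_ridge_oracle(self):
        """lambda_d=lambda_t=0 reduces the baseline to alternating ridge steps."""
        Y, KD, Kd = _random_problem(16, n=6, m=4)
        hp = HyperParams(lambda_l=0.6, lambda_d=0.0, lambda_t=0.0, k=2, max_iter=30)
        res = fit_cmf(Y, KD, Kd, hp)
        A, B = (fp := svd_init(Y, 2)).A, fp.B
        for _ in range(res.iterations):
            A = Y @ B @ np.linalg.inv(B.T @ B + 0.6 * np.eye(2))
            B = Y.T @ A @ np.linalg.inv(A.T @ A + 0.6 * np.eye(2))
        np.testing.assert_allclose(res.factors.A, A, atol=1e-8)
        np.testing.assert_allclose(res.factors.B, B, atol=1e-8)

    def test_shape_contract(self):
        Y, KD, Kd = _random_problem(17, n=9, m=6)
        res = fit_cmf(Y, KD, Kd, HyperParams(k=3))
        assert res.factors.A.shape == (9, 3) and res.factors.B.shape == (6, 3)


class TestPredictScores:
    def test_identity_factors(self):
        fp = FactorPair(np.eye(4), np.eye(4))
        np.testing.assert_array_equal(predict_scores(fp), np.eye(4))

    def test_invariant_under_orthogonal_rotation(self):
        rng = np.random.default_rng(18)
        fp = FactorPair(rng.normal(size=(7, 3)), rng.normal(size=(5, 3)))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        fp_rot = FactorPair(fp.A @ Q, fp.B @ Q)
        np.testing.assert_allclose(predict_scores(fp_rot), predict_scores(fp), atol=1e-10)

    def test_shape(self):
        fp = FactorPair(np.ones((7, 2)), np.ones((5, 2)))
        assert predict_scores(fp).shape == (7, 5)
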