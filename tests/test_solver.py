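import logging

import numpy as np
import pytest
from scipy.optimize import minimize

from msnr import (
    CovariateTable,
    SolverConfig,
    build_membership,
    compute_block_summary,
    fit_msnr,
    gamma_update,
    lambda_max,
    theta_update,
)
from msnr.solver import BlockSummary, _block_pairs

from _oracles import brute_force_block_means, fista_minimize, reference_objective
from conftest import random_instance


class TestThetaUpdate:
    def test_identity_at_zero_penalty(self, rng):
        R = rng.normal(size=(5, 5))
        R = R + R.T
        assert np.array_equal(theta_update(R, 0.0, 3), R)

    def test_full_shrinkage(self, rng):
        R = rng.normal(size=(4, 4))
        R = R + R.T
        # tiny bump keeps lam/(2n) >= max|eig| under floating-point rounding
        lam = 2 * 2 * np.max(np.abs(np.linalg.eigvalsh(R))) * (1 + 1e-12)  # n = 2
        assert np.all(theta_update(R, lam, 2) == 0.0)

    def test_diag_3_1_shrinks_to_2_0(self):
        out = theta_update(np.diag([3.0, 1.0]), 2.0, 1)
        assert np.allclose(np.sort(np.linalg.eigvalsh(out)), [0.0, 2.0], atol=1e-12)

    def test_matches_numerical_minimizer(self):
        # oracle: scalar minimization over symmetric 2x2 matrices
        R = np.diag([3.0, 1.0])
        n, lam1 = 1, 2.0

        def obj(v):
            T = np.array([[v[0], v[1]], [v[1], v[2]]])
            return n * np.sum((T - R) ** 2) + lam1 * np.sum(
                np.linalg.svd(T, compute_uv=False)
            )

        res = minimize(obj, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        T_star = np.array([[res.x[0], res.x[1]], [res.x[1], res.x[2]]])
        assert np.allclose(theta_update(R, lam1, n), T_star, atol=1e-4)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            theta_update(np.array([[0.0, 1.0], [0.0, 0.0]]), 1.0, 1)


class TestBlockSummary:
    def test_two_node_community(self):
        part = build_membership({0: "a", 1: "a"}, [0, 1])
        vals = np.array([[[0.0, 0.5], [0.5, 0.0]]])
        s = compute_block_summary(vals, part)
        assert s.block_counts[0] == 2
        assert np.isclose(s.block_means[0, 0], 0.5)

    def test_constant_matrix(self):
        part = build_membership({j: j % 2 for j in range(6)}, list(range(6)))
        M = np.full((6, 6), 3.25)
        np.fill_diagonal(M, 0.0)
        s = compute_block_summary(M[None], part)
        assert np.allclose(s.block_means, 3.25)

    def test_matches_brute_force(self, rng):
        part = build_membership({j: j % 2 for j in range(6)}, list(range(6)))
        M = rng.normal(size=(3, 6, 6))
        M = M + M.transpose(0, 2, 1)
        idx = np.arange(6)
        M[:, idx, idx] = 0.0
        s = compute_block_summary(M, part)
        means, counts, pairs = brute_force_block_means(M, part.node_communities(), 2)
        assert np.allclose(s.block_means, means)
        assert np.allclose(s.block_counts, counts)
        assert [tuple(pr) for pr in s.pairs] == pairs

    def test_singleton_block_dropped(self):
        part = build_membership({0: "a", 1: "a", 2: "b"}, [0, 1, 2])
        M = np.ones((3, 3))
        np.fill_diagonal(M, 0.0)
        s = compute_block_summary(M[None], part)
        within_b = [i for i, (k, kk) in enumerate(s.pairs) if (k, kk) == (1, 1)][0]
        assert s.block_counts[within_b] == 0
        assert s.block_means[0, within_b] == 0.0


def _summary_for(ybar, m, K=1):
    pairs = _block_pairs(K)[: ybar.shape[1]]
    return BlockSummary(
        block_means=ybar, block_counts=np.asarray(m, dtype=float),
        pairs=pairs, n_communities=K,
    )


class TestGammaUpdate:
    def test_zero_solution_condition(self, rng):
        n, q = 8, 2
        X = rng.normal(size=(n, q))
        X = (X - X.mean(0)) / X.std(0)
        ybar = rng.normal(size=(n, 1))
        m = [3.0]
        lam2_max = 2 * m[0] * np.max(np.abs(X.T @ ybar))
        out = gamma_update(_summary_for(ybar, m), X, lam2_max, config=SolverConfig())
        assert np.all(out == 0.0)

    def test_ols_limit(self, rng):
        n = 10
        x = rng.normal(size=(n, 1))
        x = (x - x.mean()) / x.std()
        ybar = rng.normal(size=(n, 1))
        out = gamma_update(_summary_for(ybar, [5.0]), x, 0.0)
        slope = float(x[:, 0] @ ybar[:, 0] / (x[:, 0] @ x[:, 0]))
        assert np.isclose(out[0, 0, 0], slope, atol=1e-10)

    def test_matches_convex_oracle(self):
        # one block with m = 2, n = 4, q = 2, lambda2 = 0.5
        rng = np.random.default_rng(99)
        X = rng.normal(size=(4, 2))
        X = (X - X.mean(0)) / X.std(0)
        ybar = rng.normal(size=(4, 1))
        m, lam2 = 2.0, 0.5

        def obj(g):
            return m * np.sum((ybar[:, 0] - X @ g) ** 2) + lam2 * np.sum(np.abs(g))

        res = minimize(obj, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000})
        out = gamma_update(_summary_for(ybar, [m]), X, lam2)
        assert np.allclose(out[:, 0, 0], res.x, atol=1e-6)

    def test_warns_on_uncentered(self, rng):
        X = rng.normal(loc=5.0, size=(6, 1))
        ybar = rng.normal(size=(6, 1))
        with pytest.warns(UserWarning, match="centered"):
            gamma_update(_summary_for(ybar, [2.0]), X, 0.1)

    def test_zero_variance_covariate_errors(self):
        X = np.ones((5, 1))
        ybar = np.zeros((5, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            gamma_update(_summary_for(ybar, [2.0]), X, 0.1)


class TestFitMSNR:
    def test_fully_shrunk_solution(self, small_instance):
        A, X, part = small_instance
        Xs = X.standardize()
        lam1, lam2 = lambda_max(A, Xs, part)
        model = fit_msnr(A, Xs, part, 10 * lam1, 10 * lam2)
        assert np.all(model.theta == 0.0)
        assert np.all(model.gammas == 0.0)
        assert np.isclose(
            model.diagnostics.objective_trajectory[-1], np.sum(A.values**2)
        )

    def test_noiseless_exact_recovery(self):
        from msnr import generate_dataset

        A, X, part, _ = generate_dataset(
            n=20, p=12, K=3, d=2, q=2, noise_sd=0.0, seed=1
        )
        model = fit_msnr(A, X, part, 0.0, 0.0)
        assert model.diagnostics.objective_trajectory[-1] < 1e-6 * np.sum(A.values**2)

    def test_trajectory_non_increasing(self):
        for seed in range(5):
            A, X, part = random_instance(seed, n=6, p=8, K=3, q=2)
            model = fit_msnr(A, X, part, 1.0, 0.5)
            traj = np.array(model.diagnostics.objective_trajectory)
            assert np.all(np.diff(traj) <= 1e-10 * np.maximum(1.0, traj[:-1]))
            assert len(traj) == model.diagnostics.n_iterations + 1

    def test_symmetry_preserved(self, small_instance):
        A, X, part = small_instance
        model = fit_msnr(A, X, part, 0.3, 0.2)
        assert np.allclose(model.theta, model.theta.T, atol=1e-14)
        for g in model.gammas:
            assert np.allclose(g, g.T, atol=1e-14)

    def test_nonconvergence_warns_not_raises(self, small_instance, caplog):
        A, X, part = small_instance
        config = SolverConfig(tol=1e-16, max_iter=1)
        with caplog.at_level(logging.WARNING, logger="msnr.solver"):
            model = fit_msnr(A, X, part, 0.1, 0.1, config)
        assert not model.diagnostics.converged
        assert any("converge" in r.message for r in caplog.records)

    def test_matches_global_optimum_oracle(self):
        A, X, part = random_instance(11, n=4, p=6, K=2, q=2)
        Xs = X.standardize()
        lam1, lam2 = 3.0, 1.0
        model = fit_msnr(A, Xs, part, lam1, lam2, SolverConfig(tol=1e-12))
        _, _, best = fista_minimize(
            A.values, Xs.centered_scaled, part.membership, lam1, lam2
        )
        ours = reference_objective(
            A.values, Xs.centered_scaled, part.membership,
            model.theta, model.gammas, lam1, lam2,
        )
        assert abs(ours - best) <= 1e-5 * max(best, 1.0)

    def test_singleton_community_gamma_fixed_zero(self):
        A, X, _ = random_instance(13, n=5, p=5, K=2, q=1)
        part = build_membership(
            {f"n{j:04d}": ("solo" if j == 0 else "rest") for j in range(5)},
            [f"n{j:04d}" for j in range(5)],
        )
        model = fit_msnr(A, X, part, 0.1, 0.01)
        k_solo = list(part.community_labels).index("solo")
        assert np.all(model.gammas[:, k_solo, k_solo] == 0.0)

    def test_trace_diagnostic_recorded(self, small_instance):
        A, X, part = small_instance
        model = fit_msnr(A, X, part, 0.5, 0.5)
        W = part.membership
        assert np.isclose(
            model.diagnostics.trace_WtThetaW, np.trace(W.T @ model.theta @ W)
        )


class TestLambdaMax:
    def test_gamma_zero_at_lambda2_max(self, small_instance):
        A, X, part = small_instance
        Xs = X.standardize()
        lam1, lam2 = lambda_max(A, Xs, part)
        summary = compute_block_summary(A.values, part)
        out = gamma_update(summary, Xs.centered_scaled, lam2)
        assert np.all(out == 0.0)

    def test_theta_zero_at_lambda1_max(self, small_instance):
        A, X, part = small_instance
        Xs = X.standardize()
        lam1, _ = lambda_max(A, Xs, part)
        Abar = A.values.mean(axis=0)
        assert np.allclose(theta_update(Abar, lam1, A.n_subjects), 0.0, atol=1e-12)

    def test_halving_lambda2_gives_nonzero_gamma(self, small_instance):
        A, X, part = small_instance
        Xs = X.standardize()
        _, lam2 = lambda_max(A, Xs, part)
        model = fit_msnr(A, Xs, part, 0.0, lam2 / 2.0)
        assert np.any(model.gammas != 0.0)

    def test_sparsity_nonincreasing_along_path(self):
        A, X, part = random_instance(21, n=8, p=10, K=3, q=2)
        Xs = X.standardize()
        _, lam2 = lambda_max(A, Xs, part)
        counts = []
        for lam in np.geomspace(1e-4 * lam2, lam2, 10):
            model = fit_msnr(A, Xs, part, 0.0, lam, SolverConfig(tol=1e-10))
            counts.append(int(np.sum(model.gammas != 0)))
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestSupportRecovery:
    def test_sign_and_correlation_at_moderate_noise(self):
        from msnr import generate_dataset

        A, X, part, truth = generate_dataset(
            n=100, p=30, K=3, d=2, q=2, gamma_sparsity=0.5,
            effect_size=0.5, noise_sd=0.5, seed=4,
        )
        model = fit_msnr(A, X, part, 1.0, 1.0)
        gt, ge = truth.gammas_true.ravel(), model.gammas.ravel()
        assert np.corrcoef(gt, ge)[0, 1] >= 0.9
        support = gt != 0
        assert np.mean(np.sign(ge[support]) == np.sign(gt[support])) >= 0.9
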