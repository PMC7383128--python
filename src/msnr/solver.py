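"""Block coordinate descent for the penalized network-regression problem.

The convex objective

    sum_i ||A^i - Theta - sum_f x_if zdiag(W Gamma^f W^T)||_F^2
        + lambda1 ||Theta||_*  + lambda2 sum_f ||Gamma^f||_1

is minimized by alternating two exact block updates:

* Theta-block: with Gamma fixed, the minimizer is eigenvalue
  soft-thresholding of the mean residual matrix at level lambda1 / (2n).
* Gamma-block: the loss decouples over unordered community pairs
  (k <= k').  For each pair the problem is a weighted lasso on the
  per-subject block means of the residual, with weight m_kk' equal to the
  number of (ordered) off-diagonal entries in the block; for k != k' the
  factor-2 double count of the two ordered blocks appears identically in
  the loss and in the matrix l1 penalty and cancels.  Each weighted lasso
  is solved by cyclic coordinate descent with exact scalar soft-threshold
  updates, vectorized across blocks.

Both updates are exact block minimizers, so the objective is
non-increasing at every half-step and, the problem being convex with a
separable nonsmooth part, the iterates converge to a global optimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    AdjacencyStack,
    CommunityPartition,
    CovariateTable,
    FitDiagnostics,
    MSNRModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "BlockSummary",
    "theta_update",
    "compute_block_summary",
    "gamma_update",
    "fit_msnr",
    "lambda_max",
]


@dataclass
class SolverConfig:
    """Tolerances and iteration caps for the block coordinate descent."""

    tol: float = 1e-6
    max_iter: int = 200
    inner_tol: float = 1e-8
    inner_max_iter: int = 1000

    def __post_init__(self):
        if min(self.tol, self.inner_tol) <= 0 or min(self.max_iter, self.inner_max_iter) <= 0:
            raise ValueError("solver config values must be positive")


@dataclass
class BlockSummary:
    """Per-subject means of a residual stack over community blocks.

    ``pairs`` lists the B = K(K+1)/2 unordered community pairs (k <= k') in
    lexicographic order.  ``block_counts[b]`` is m_kk' = |C_k||C_k'| for
    k != k' and |C_k|(|C_k| - 1) for k = k' (the off-diagonal entry count);
    singleton within-blocks have m = 0 and are excluded from the Gamma
    problem (their coefficients stay fixed at 0).
    """

    block_means: np.ndarray  # n x B
    block_counts: np.ndarray  # B
    pairs: np.ndarray  # B x 2
    n_communities: int


def _block_pairs(K: int) -> np.ndarray:
    return np.array([(k, kk) for k in range(K) for kk in range(k, K)], dtype=int)


def _block_counts(sizes: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    s = np.asarray(sizes, dtype=float)
    k, kk = pairs[:, 0], pairs[:, 1]
    m = np.where(k == kk, s[k] * (s[k] - 1), s[k] * s[kk])
    return m


def _ordered_entry_counts(m: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Number of ordered off-diagonal entries per unordered block."""
    between = pairs[:, 0] != pairs[:, 1]
    return np.where(between, 2.0 * m, m)


def _block_ordsums(values: np.ndarray, W: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Sum of off-diagonal entries over each unordered block, both orders.

    ``values`` is (n, p, p) or (p, p); returns (n, B) or (B,).
    """
    single = values.ndim == 2
    V = values[None] if single else values
    T = np.matmul(W.T, np.matmul(V, W))  # n x K x K block sums incl. diagonal
    idx = np.arange(V.shape[1])
    diag_by_comm = np.matmul(V[:, idx, idx], W)  # n x K
    k, kk = pairs[:, 0], pairs[:, 1]
    within = k == kk
    out = np.where(within[None, :], T[:, k, kk] - diag_by_comm[:, k], 2.0 * T[:, k, kk])
    return out[0] if single else out


def theta_update(Rbar: np.ndarray, lambda1: float, n: int) -> np.ndarray:
    """Exact Theta-block minimizer: eigenvalue soft-thresholding.

    Solves ``argmin_Theta n||Theta - Rbar||_F^2 + lambda1 ||Theta||_*`` for
    symmetric ``Rbar`` by shrinking each eigenvalue toward zero by
    ``lambda1 / (2n)`` and zeroing those at or below the threshold.
    """
    Rbar = np.asarray(Rbar, dtype=float)
    if not np.allclose(Rbar, Rbar.T, atol=1e-8, rtol=0.0):
        raise ValueError("theta_update requires a symmetric matrix")
    thr = lambda1 / (2.0 * n)
    if thr == 0.0:
        return Rbar.copy()
    d, U = np.linalg.eigh(0.5 * (Rbar + Rbar.T))
    d_shr = np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)
    Theta = (U * d_shr) @ U.T
    return 0.5 * (Theta + Theta.T)


def compute_block_summary(residuals, partition: CommunityPartition) -> BlockSummary:
    """Block means of a symmetric zero-diagonal residual stack."""
    values = residuals.values if isinstance(residuals, AdjacencyStack) else np.asarray(residuals, dtype=float)
    if values.ndim == 2:
        values = values[None]
    W = partition.membership
    pairs = _block_pairs(partition.n_communities)
    m = _block_counts(partition.sizes, pairs)
    c = _ordered_entry_counts(m, pairs)
    ordsums = _block_ordsums(values, W, pairs)
    means = np.zeros_like(ordsums)
    np.divide(ordsums, c[None, :], out=means, where=c[None, :] > 0)
    return BlockSummary(
        block_means=means,
        block_counts=m,
        pairs=pairs,
        n_communities=partition.n_communities,
    )


def _check_standardized(X: np.ndarray) -> None:
    col_scale = np.maximum(np.abs(X).max(axis=0, initial=0.0), 1.0)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance covariate column")
    if np.any(np.abs(X.mean(axis=0)) > 1e-6 * col_scale):
        warnings.warn("covariate matrix does not appear to be centered", stacklevel=3)


def _gamma_cd(
    Ybar: np.ndarray,
    X: np.ndarray,
    m: np.ndarray,
    lambda2: float,
    gmat: np.ndarray,
    config: SolverConfig,
) -> np.ndarray:
    """Cyclic coordinate descent on the decoupled weighted lassos.

    ``Ybar`` (n x B) block means, ``gmat`` (q x B) warm start, modified in
    place and returned.  Blocks with m == 0 are held at zero.
    """
    n, q = X.shape
    active = m > 0
    sx2 = np.einsum("ij,ij->j", X, X)  # per-covariate sum of squares
    U = X @ gmat  # n x B fitted block means
    thr = np.zeros_like(m)
    np.divide(lambda2, 2.0 * m, out=thr, where=active)
    for _ in range(config.inner_max_iter):
        max_delta = 0.0
        for f in range(q):
            rho = X[:, f] @ (Ybar - U) + sx2[f] * gmat[f]
            new = np.sign(rho) * np.maximum(np.abs(rho) - thr, 0.0) / sx2[f]
            new[~active] = 0.0
            delta = new - gmat[f]
            nz = delta != 0.0
            if np.any(nz):
                U += np.outer(X[:, f], delta)
                gmat[f] = new
                max_delta = max(max_delta, float(np.abs(delta).max()))
        if max_delta < config.inner_tol:
            break
    return gmat


def _gmat_to_gammas(gmat: np.ndarray, pairs: np.ndarray, K: int) -> np.ndarray:
    q = gmat.shape[0]
    gammas = np.zeros((q, K, K))
    k, kk = pairs[:, 0], pairs[:, 1]
    gammas[:, k, kk] = gmat
    gammas[:, kk, k] = gmat
    return gammas


def _gammas_to_gmat(gammas: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    return gammas[:, pairs[:, 0], pairs[:, 1]].copy()


def gamma_update(
    summary: BlockSummary,
    X: np.ndarray,
    lambda2: float,
    warm_start: np.ndarray | None = None,
    config: SolverConfig | None = None,
) -> np.ndarray:
    """Exact Gamma-block minimizer given residual block means.

    Returns a (q, K, K) stack of symmetric matrices solving, independently
    for every unordered pair (k <= k') with m_kk' > 0,

        argmin_g  m_kk' * sum_i (ybar_ikk' - x_i^T g)^2 + lambda2 ||g||_1.
    """
    config = config or SolverConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_standardized(X)
    K = summary.n_communities
    q = X.shape[1]
    if warm_start is None:
        gmat = np.zeros((q, summary.pairs.shape[0]))
    else:
        warm = np.asarray(warm_start, dtype=float)
        gmat = _gammas_to_gmat(warm if warm.ndim == 3 else warm[None], summary.pairs)
    gmat = _gamma_cd(summary.block_means, X, summary.block_counts, lambda2, gmat, config)
    return _gmat_to_gammas(gmat, summary.pairs, K)


def _theta_ordsums(theta: np.ndarray, W: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    return _block_ordsums(theta, W, pairs)


@dataclass
class _FitCache:
    """Per-dataset precomputations reused across penalty values.

    Valid only for one (adjacency stack, partition) pair; cross-validation
    builds one per fold and reuses it for every grid cell.
    """

    pairs: np.ndarray
    m: np.ndarray
    c: np.ndarray
    ordsums_A: np.ndarray  # n x B
    Abar: np.ndarray
    sum_A2: float
    eig_d: np.ndarray  # eigendecomposition of Abar
    eig_U: np.ndarray


def _prepare_fit(A: AdjacencyStack, partition: CommunityPartition) -> _FitCache:
    W = partition.membership
    pairs = _block_pairs(partition.n_communities)
    m = _block_counts(partition.sizes, pairs)
    Abar = A.values.mean(axis=0)
    d, U = np.linalg.eigh(Abar)
    return _FitCache(
        pairs=pairs,
        m=m,
        c=_ordered_entry_counts(m, pairs),
        ordsums_A=_block_ordsums(A.values, W, pairs),
        Abar=Abar,
        sum_A2=float(np.sum(A.values**2)),
        eig_d=d,
        eig_U=U,
    )


def fit_msnr(
    A: AdjacencyStack,
    X: CovariateTable,
    partition: CommunityPartition,
    lambda1: float,
    lambda2: float,
    config: SolverConfig | None = None,
    _cache: _FitCache | None = None,
) -> MSNRModel:
    """Fit the model by block coordinate descent from Theta = 0, Gamma = 0.

    ``X`` is standardized with its own statistics unless it already carries
    standardization state (e.g. transformed with training-fold statistics).
    Alternates the Gamma update (residuals A^i - Theta) with the Theta
    update (residuals A^i - fitted community effects) until the relative
    objective change drops below ``config.tol``.  Non-convergence yields a
    model with ``diagnostics.converged = False`` and a logged warning, not
    an exception.
    """
    config = config or SolverConfig()
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be nonnegative")
    n, p = A.n_subjects, A.n_nodes
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if partition.n_nodes != p:
        raise ValueError("partition does not match adjacency node count")
    if X.n_subjects != n:
        raise ValueError("covariate table does not match adjacency stack")
    Xtab = X if X.is_standardized else X.standardize()
    Xs = Xtab.centered_scaled
    q = Xs.shape[1]
    W = partition.membership
    K = partition.n_communities
    cache = _cache if _cache is not None else _prepare_fit(A, partition)
    pairs, m, c = cache.pairs, cache.m, cache.c
    active = c > 0
    ordsums_A, Abar, sum_A2 = cache.ordsums_A, cache.Abar, cache.sum_A2
    xbar = Xs.mean(axis=0)  # ~0 after centering; kept for exactness
    # spectral scale below which the Gamma-mean coupling is numerical noise
    # and the cached eigendecomposition of Abar can be reused
    eig_reuse_tol = 1e-13 * max(np.max(np.abs(cache.eig_d)), 1.0)

    theta = np.zeros((p, p))
    theta_eigs = np.zeros(p)
    gmat = np.zeros((q, pairs.shape[0]))

    def current_objective() -> float:
        # loss decomposed over community blocks; O(nB + p^2) per call
        ord_theta = _theta_ordsums(theta, W, pairs)
        ordsums_R = ordsums_A - ord_theta[None, :]
        ybar = np.zeros_like(ordsums_R)
        np.divide(ordsums_R, c[None, :], out=ybar, where=active[None, :])
        Ufit = Xs @ gmat
        loss_theta = sum_A2 - 2.0 * n * float(np.sum(Abar * theta)) + n * float(np.sum(theta**2))
        cross = -2.0 * float(np.einsum("ib,ib,b->", ybar, Ufit, c))
        quad = float(np.einsum("ib,ib,b->", Ufit, Ufit, c))
        pen = lambda1 * float(np.sum(np.abs(theta_eigs))) + lambda2 * float(
            np.sum(np.abs(gmat) * np.where(pairs[:, 0] != pairs[:, 1], 2.0, 1.0)[None, :])
        )
        return loss_theta + cross + quad + pen

    obj = current_objective()
    trajectory = [obj]
    converged = False
    rel = np.inf
    thr1 = lambda1 / (2.0 * n)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        # Gamma step on residuals A - Theta
        ord_theta = _theta_ordsums(theta, W, pairs)
        ordsums_R = ordsums_A - ord_theta[None, :]
        ybar = np.zeros_like(ordsums_R)
        np.divide(ordsums_R, c[None, :], out=ybar, where=active[None, :])
        gmat = _gamma_cd(ybar, Xs, m, lambda2, gmat, config)

        # Theta step on residuals A - fitted community effects; with
        # centered covariates the mean community effect is ~0, so the
        # cached eigendecomposition of Abar applies
        Gbar = np.tensordot(xbar, _gmat_to_gammas(gmat, pairs, K), axes=1)
        if np.max(np.abs(Gbar), initial=0.0) <= eig_reuse_tol:
            d, Uvec = cache.eig_d, cache.eig_U
        else:
            M = W @ Gbar @ W.T
            np.fill_diagonal(M, 0.0)
            Rbar = Abar - M
            d, Uvec = np.linalg.eigh(0.5 * (Rbar + Rbar.T))
        theta_eigs = np.sign(d) * np.maximum(np.abs(d) - thr1, 0.0)
        theta = (Uvec * theta_eigs) @ Uvec.T
        theta = 0.5 * (theta + theta.T)

        new_obj = current_objective()
        rel = abs(new_obj - obj) / max(1.0, obj)
        trajectory.append(new_obj)
        obj = new_obj
        if rel < config.tol:
            converged = True
            break

    if not converged:
        logger.warning(
            "solver did not converge in %d iterations (relative change %.3e)",
            config.max_iter,
            rel,
        )

    gammas = _gmat_to_gammas(gmat, pairs, K)
    diagnostics = FitDiagnostics(
        objective_trajectory=trajectory,
        n_iterations=n_iter,
        converged=converged,
        final_relative_change=float(rel),
        trace_WtThetaW=float(np.trace(W.T @ theta @ W)),
    )
    return MSNRModel(
        theta=theta,
        gammas=gammas,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        partition=partition,
        x_center=Xtab.center,
        x_scale=Xtab.scale,
        covariate_names=Xtab.covariate_names,
        diagnostics=diagnostics,
    )


def lambda_max(
    A: AdjacencyStack,
    X: CovariateTable,
    partition: CommunityPartition,
) -> tuple[float, float]:
    """Smallest penalties that zero each block at the start (Theta=0, Gamma=0).

    ``lambda1_max = 2n max|eig(Abar)|`` makes the first Theta update return
    zero with Gamma = 0; ``lambda2_max = max_{k<=k',f} 2 m_kk' |sum_i x_if
    ybar^i_kk'|`` makes Gamma = 0 optimal for the first Gamma update.
    """
    Xtab = X if X.is_standardized else X.standardize()
    Xs = Xtab.centered_scaled
    n = A.n_subjects
    summary = compute_block_summary(A.values, partition)
    corr = Xs.T @ summary.block_means  # q x B
    lam2 = float(np.max(2.0 * summary.block_counts[None, :] * np.abs(corr)))
    Abar = A.values.mean(axis=0)
    lam1 = float(2.0 * n * np.max(np.abs(np.linalg.eigvalsh(Abar))))
    return lam1, lam2
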