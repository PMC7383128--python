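"""Synthetic cohorts drawn from the generative model with known truth.

Each dataset is assembled as ``A^i = Theta* + sum_f x_if zdiag(W Gamma*^f
W^T) + eps^i`` with ``Theta* = V V^T`` for a low-rank factor V, sparse
symmetric ``Gamma*`` matrices, standardized Gaussian covariates, and
symmetric Gaussian edge noise.  All randomness flows from one seed, so a
dataset is bit-reproducible.  The design axes (signal-to-noise via
``effect_size``/``noise_sd``, observations-to-features via n vs p, q) are
artifact choices, documented here rather than taken from any external
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AdjacencyStack, CommunityPartition, CovariateTable, build_membership

__all__ = ["SyntheticTruth", "generate_dataset", "null_dataset", "near_equal_partition"]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a synthetic cohort."""

    V: np.ndarray  # p x d low-rank factor
    theta_true: np.ndarray  # p x p = V V^T (optionally trace-adjusted)
    gammas_true: np.ndarray  # q x K x K symmetric, sparse
    noise_sd: float
    X: np.ndarray  # n x q standardized covariates
    partition: CommunityPartition
    seed: int


def near_equal_partition(p: int, K: int) -> CommunityPartition:
    """p nodes into K contiguous communities with sizes differing by <= 1."""
    if not 1 <= K <= p:
        raise ValueError(f"need 1 <= K <= p, got K={K}, p={p}")
    node_ids = [f"n{j:04d}" for j in range(p)]
    bounds = np.linspace(0, p, K + 1).round().astype(int)
    table = {}
    for k in range(K):
        for j in range(bounds[k], bounds[k + 1]):
            table[node_ids[j]] = f"c{k:02d}"
    return build_membership(table, node_ids)


def _symmetric_noise(rng: np.random.Generator, p: int, sd: float) -> np.ndarray:
    E = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    E[iu] = rng.normal(0.0, sd, size=iu[0].size) if sd > 0 else 0.0
    return E + E.T


def _sparse_gamma(rng: np.random.Generator, K: int, sparsity: float, effect: float) -> np.ndarray:
    iu = np.triu_indices(K)  # unique entries incl. diagonal
    nonzero = rng.random(iu[0].size) >= sparsity
    signs = rng.choice([-1.0, 1.0], size=iu[0].size)
    vals = np.where(nonzero, signs * effect, 0.0)
    G = np.zeros((K, K))
    G[iu] = vals
    G = np.triu(G) + np.triu(G, k=1).T
    return G


def generate_dataset(
    n: int = 200,
    p: int = 60,
    K: int = 6,
    d: int = 3,
    q: int = 3,
    gamma_sparsity: float = 0.7,
    effect_size: float = 0.5,
    noise_sd: float = 0.5,
    theta_scale: float = 1.0,
    seed: int = 0,
    trace_adjust: bool = False,
) -> tuple[AdjacencyStack, CovariateTable, CommunityPartition, SyntheticTruth]:
    """Draw one cohort with known low-rank mean and sparse block effects.

    Covariates are i.i.d. standard normal, column-standardized.  V has
    i.i.d. normal(0, theta_scale^2 / sqrt(d)) entries.  Each Gamma* upper
    triangle entry (diagonal included) is nonzero with probability
    1 - gamma_sparsity, with value +/- effect_size at a random sign.
    ``trace_adjust=True`` subtracts a block-constant matrix from Theta* so
    Tr(W^T Theta* W) = 0.
    """
    if not (0 <= gamma_sparsity <= 1):
        raise ValueError("gamma_sparsity must lie in [0, 1]")
    if not 1 <= d < p:
        raise ValueError("need 1 <= d < p")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    partition = near_equal_partition(p, K)
    rng = np.random.default_rng(seed)

    Xraw = rng.normal(size=(n, q))
    Xraw = (Xraw - Xraw.mean(axis=0)) / Xraw.std(axis=0)
    X = CovariateTable(Xraw, covariate_names=[f"x{f}" for f in range(q)])

    V = rng.normal(0.0, theta_scale / d**0.25, size=(p, d))
    theta = V @ V.T
    W = partition.membership
    if trace_adjust:
        # subtract c * W S W^T with S chosen so Tr(W^T theta W) becomes 0
        sizes = partition.sizes.astype(float)
        tr = float(np.trace(W.T @ theta @ W))
        theta = theta - (tr / float(np.sum(sizes**2))) * (W @ W.T)

    gammas = np.stack([_sparse_gamma(rng, K, gamma_sparsity, effect_size) for _ in range(q)])

    signal = np.einsum("jk,fkl,ml->fjm", W, gammas, W)  # q x p x p
    idx = np.arange(p)
    signal[:, idx, idx] = 0.0
    values = theta[None] + np.tensordot(Xraw, signal, axes=([1], [0]))
    for i in range(n):
        values[i] += _symmetric_noise(rng, p, noise_sd)
    values[:, idx, idx] = 0.0
    values = 0.5 * (values + values.transpose(0, 2, 1))

    A = AdjacencyStack(values, validate=False)
    A.values.flags.writeable = False
    truth = SyntheticTruth(
        V=V,
        theta_true=theta,
        gammas_true=gammas,
        noise_sd=noise_sd,
        X=Xraw,
        partition=partition,
        seed=seed,
    )
    return A, X, partition, truth


def null_dataset(
    n: int = 200,
    p: int = 60,
    K: int = 6,
    d: int = 3,
    q: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[AdjacencyStack, CovariateTable, CommunityPartition, SyntheticTruth]:
    """Cohort with no covariate effect at all (every Gamma* = 0)."""
    return generate_dataset(
        n=n, p=p, K=K, d=d, q=q,
        gamma_sparsity=1.0, effect_size=0.0, noise_sd=noise_sd, seed=seed,
    )
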