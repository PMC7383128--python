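"""Single-scale comparator models: mass-univariate per-edge OLS and the
community-mean OLS, each with FDR correction and edge-level out-of-sample
prediction error computed by the same routine as the multi-scale model.

Covariates enter these baselines unstandardized, with an intercept (the
``edge ~ covariates`` formula convention); each fitted object exposes
``predict_stack`` so ``model_selection.prediction_error`` scores all model
families identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AdjacencyStack, CommunityPartition, CovariateTable
from .model_selection import prediction_error

__all__ = [
    "EdgeModelFit",
    "CommunityModelFit",
    "ols_fit",
    "community_means",
    "community_mean_columns",
    "fdr_correct",
    "edge_model",
    "community_model",
]


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(X.shape[0]), X])


def _ols_multi(Y: np.ndarray, design: np.ndarray):
    """OLS for many responses sharing one design; returns (beta, se, pvals).

    ``Y`` is n x E, ``design`` n x d (intercept included by the caller).
    Outputs are d x E.  Perfect fits (zero residual variance) get p = 0 for
    nonzero coefficients and p = 1 for zero ones.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, d = design.shape
    if n <= d:
        raise ValueError(f"need n > number of design columns ({n} <= {d})")
    XtX = design.T @ design
    rank = np.linalg.matrix_rank(XtX)
    if rank < d:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (design.T @ Y)
    resid = Y - design @ beta
    dof = n - d
    sigma2 = np.sum(resid**2, axis=0) / dof  # E
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # d x E
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    exact = se == 0.0
    pvals[exact & (beta != 0.0)] = 0.0
    pvals[exact & (beta == 0.0)] = 1.0
    return beta, se, pvals


def ols_fit(y: np.ndarray, design: np.ndarray):
    """OLS of one response on a design matrix (intercept already added).

    Returns (coefficients, standard errors, two-sided t-test p-values).
    """
    y = np.asarray(y, dtype=float).ravel()
    beta, se, p = _ols_multi(y[:, None], np.asarray(design, dtype=float))
    return beta[:, 0], se[:, 0], p[:, 0]


def community_mean_columns(partition: CommunityPartition) -> list[tuple]:
    """Column labels for :func:`community_means`: K within columns (singletons
    dropped) followed by the unordered between pairs in lexicographic order."""
    K = partition.n_communities
    cols: list[tuple] = []
    for k in range(K):
        if partition.sizes[k] >= 2:
            cols.append(("within", k, k))
    for k in range(K):
        for kk in range(k + 1, K):
            cols.append(("between", k, kk))
    return cols


def community_means(A, partition: CommunityPartition) -> np.ndarray:
    """Per-subject within- and between-community mean connectivity.

    Within mean for community k averages its |C_k|(|C_k|-1) ordered
    off-diagonal entries; between mean for (k, k') averages the
    |C_k||C_k'| cross entries.  Singleton communities have no within
    edges; their columns are dropped with a warning.
    """
    values = A.values if isinstance(A, AdjacencyStack) else np.asarray(A, dtype=float)
    if values.ndim == 2:
        values = values[None]
    W = partition.membership
    sizes = np.asarray(partition.sizes)
    T = np.matmul(W.T, np.matmul(values, W))  # n x K x K block sums
    if np.any(sizes < 2):
        warnings.warn("singleton community: within-community column dropped", stacklevel=2)
    cols = []
    for kind, k, kk in community_mean_columns(partition):
        if kind == "within":
            idx = np.arange(values.shape[1])
            diag_sum = values[:, idx, idx] @ W[:, k]
            cols.append((T[:, k, k] - diag_sum) / (sizes[k] * (sizes[k] - 1)))
        else:
            cols.append(T[:, k, kk] / (sizes[k] * sizes[kk]))
    return np.column_stack(cols)


def _storey_reject(p: np.ndarray, q_level: float) -> np.ndarray:
    m = p.size
    pi0 = min(1.0, np.mean(p > 0.5) / 0.5) if m else 1.0
    pi0 = max(pi0, 1.0 / m)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    qvals = pi0 * m * ranked / np.arange(1, m + 1)
    qvals = np.minimum.accumulate(qvals[::-1])[::-1]
    reject = np.zeros(m, dtype=bool)
    reject[order] = qvals <= q_level
    return reject


def fdr_correct(p_values, q_level: float = 0.05, method: str = "bh") -> np.ndarray:
    """False-discovery-rate rejection mask.

    ``method='bh'`` is the Benjamini-Hochberg step-up (default);
    ``method='storey'`` uses a q-value with the simple pi0 estimate
    ``min(1, 2 * mean(p > 0.5))``.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, alpha=q_level, method="fdr_bh")[0]
    if method == "storey":
        return _storey_reject(p, q_level)
    raise ValueError(f"unknown FDR method: {method}")


def _sym_from_triu(vec: np.ndarray, p: int, iu) -> np.ndarray:
    M = np.zeros((p, p))
    M[iu] = vec
    return M + M.T


@dataclass
class EdgeModelFit:
    """Per-edge OLS fit: one linear model per upper-triangle edge."""

    coefficients: np.ndarray  # (q+1) x p x p symmetric (intercept first)
    p_values: np.ndarray  # q x p x p (slopes only)
    fdr_mask: np.ndarray  # q x p x p binary
    beta: np.ndarray  # (q+1) x E raw solution, intercept first
    n_nodes: int
    covariate_names: np.ndarray | None = None

    def predict_stack(self, X: CovariateTable) -> np.ndarray:
        design = add_intercept(X.raw)
        pred_edges = design @ self.beta  # n x E
        p = self.n_nodes
        iu = np.triu_indices(p, k=1)
        out = np.zeros((pred_edges.shape[0], p, p))
        out[:, iu[0], iu[1]] = pred_edges
        out += out.transpose(0, 2, 1)
        return out


@dataclass
class CommunityModelFit:
    """Community-mean OLS fit: one linear model per within/between column."""

    within_between: np.ndarray  # n x C training response matrix
    coefficients: np.ndarray  # (q+1) x K x K symmetric
    p_values: np.ndarray  # q x K x K
    fdr_mask: np.ndarray  # q x K x K
    beta: np.ndarray  # (q+1) x C
    columns: list
    partition: CommunityPartition
    covariate_names: np.ndarray | None = None

    def predict_stack(self, X: CovariateTable) -> np.ndarray:
        design = add_intercept(X.raw)
        pred_cols = design @ self.beta  # n x C
        K = self.partition.n_communities
        B = np.zeros((pred_cols.shape[0], K, K))
        for c, (_, k, kk) in enumerate(self.columns):
            B[:, k, kk] = pred_cols[:, c]
            B[:, kk, k] = pred_cols[:, c]
        W = self.partition.membership
        out = np.einsum("jk,nkl,ml->njm", W, B, W)
        idx = np.arange(out.shape[1])
        out[:, idx, idx] = 0.0
        return out


def edge_model(
    A_train: AdjacencyStack,
    X_train: CovariateTable,
    A_test: AdjacencyStack,
    X_test: CovariateTable,
    q_level: float = 0.05,
    fdr_method: str = "bh",
) -> tuple[EdgeModelFit, float]:
    """Fit one OLS per edge; FDR-correct slopes per covariate across edges.

    Out-of-sample error uses predictions from all fitted edges (not only
    the FDR-significant ones).
    """
    p = A_train.n_nodes
    iu = np.triu_indices(p, k=1)
    Y = A_train.values[:, iu[0], iu[1]]  # n x E
    design = add_intercept(X_train.raw)
    beta, _, pvals = _ols_multi(Y, design)
    q = X_train.n_covariates
    coefficients = np.stack([_sym_from_triu(beta[d], p, iu) for d in range(q + 1)])
    p_matrices = np.stack([_sym_from_triu(pvals[1 + f], p, iu) for f in range(q)])
    masks = np.stack(
        [_sym_from_triu(fdr_correct(pvals[1 + f], q_level, fdr_method).astype(float), p, iu) for f in range(q)]
    )
    fit = EdgeModelFit(
        coefficients=coefficients,
        p_values=p_matrices,
        fdr_mask=masks.astype(bool),
        beta=beta,
        n_nodes=p,
        covariate_names=X_train.covariate_names,
    )
    return fit, prediction_error(fit, A_test, X_test)


def community_model(
    A_train: AdjacencyStack,
    X_train: CovariateTable,
    A_test: AdjacencyStack,
    X_test: CovariateTable,
    partition: CommunityPartition,
    q_level: float = 0.05,
    fdr_method: str = "bh",
) -> tuple[CommunityModelFit, float]:
    """Fit one OLS per community-mean column; error is scored at the edge
    level by broadcasting each predicted block mean over its block."""
    Y = community_means(A_train, partition)
    columns = community_mean_columns(partition)
    design = add_intercept(X_train.raw)
    beta, _, pvals = _ols_multi(Y, design)
    q = X_train.n_covariates
    K = partition.n_communities
    coefficients = np.full((q + 1, K, K), np.nan)
    p_matrices = np.full((q, K, K), np.nan)
    masks = np.zeros((q, K, K), dtype=bool)
    for c, (_, k, kk) in enumerate(columns):
        for d in range(q + 1):
            coefficients[d, k, kk] = beta[d, c]
            coefficients[d, kk, k] = beta[d, c]
    for f in range(q):
        reject = fdr_correct(pvals[1 + f], q_level, fdr_method)
        for c, (_, k, kk) in enumerate(columns):
            p_matrices[f, k, kk] = pvals[1 + f, c]
            p_matrices[f, kk, k] = pvals[1 + f, c]
            masks[f, k, kk] = reject[c]
            masks[f, kk, k] = reject[c]
    fit = CommunityModelFit(
        within_between=Y,
        coefficients=coefficients,
        p_values=p_matrices,
        fdr_mask=masks,
        beta=beta,
        columns=columns,
        partition=partition,
        covariate_names=X_train.covariate_names,
    )
    return fit, prediction_error(fit, A_test, X_test)
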