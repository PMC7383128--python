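"""Domain types and the model's forward map and penalized objective.

The model for a stack of symmetric connectivity matrices ``A^i`` (one per
subject) with covariates ``x_i`` is::

    A^i = Theta + sum_f x_if * W Gamma^f W^T + noise

where ``Theta`` (p x p, symmetric) is the covariate-free mean connectivity,
``W`` (p x K, binary) maps nodes to communities, and each ``Gamma^f``
(K x K, symmetric) holds community-level covariate effects.  The fitted
estimator minimizes a squared-Frobenius loss plus a nuclear-norm penalty on
``Theta`` and an elementwise l1 penalty on the ``Gamma^f``.

Edge convention: self-connectivity is undefined, so every adjacency
diagonal is zero and the community-effect term ``W Gamma^f W^T`` has its
diagonal zeroed before entering the loss.  The diagonal of ``Theta`` is
kept in the loss (compared against the zero diagonal of ``A^i``), which
preserves the exact closed-form block updates of the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdjacencyStack",
    "CommunityPartition",
    "CovariateTable",
    "FitDiagnostics",
    "MSNRModel",
    "build_membership",
    "community_effect_matrix",
    "nuclear_norm_symmetric",
    "objective",
    "predict",
]


class UnassignedNodeError(KeyError):
    """A node in the adjacency container has no community assignment."""


def _check_symmetric(M: np.ndarray, tol: float = 1e-8, name: str = "matrix") -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.all(np.abs(M - M.T) <= tol):
        raise ValueError(f"{name} is not symmetric within {tol}")


@dataclass
class AdjacencyStack:
    """n symmetric p x p connectivity matrices with zero diagonals.

    Parameters
    ----------
    values : ndarray of shape (n, p, p)
        Connectivity weights (e.g. Fisher-z correlations). Each slice must
        be symmetric with zero diagonal; this is validated at construction.
    subject_ids : sequence of n labels
    node_ids : sequence of p labels
    """

    values: np.ndarray
    subject_ids: np.ndarray
    node_ids: np.ndarray

    def __init__(self, values, subject_ids=None, node_ids=None, validate: bool = True):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or values.shape[1] != values.shape[2]:
            raise ValueError(f"expected (n, p, p) array, got shape {values.shape}")
        n, p = values.shape[0], values.shape[1]
        if subject_ids is None:
            subject_ids = [f"s{i:04d}" for i in range(n)]
        if node_ids is None:
            node_ids = [f"n{j:04d}" for j in range(p)]
        self.subject_ids = np.asarray(subject_ids)
        self.node_ids = np.asarray(node_ids)
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match stack")
        if len(self.node_ids) != p:
            raise ValueError("node_ids length does not match stack")
        if validate:
            if not np.all(np.isfinite(values)):
                raise ValueError("adjacency stack contains non-finite entries")
            if not np.allclose(values, values.transpose(0, 2, 1), atol=1e-8, rtol=0.0):
                raise ValueError("adjacency slices are not symmetric within 1e-8")
            values = 0.5 * (values + values.transpose(0, 2, 1))
            idx = np.arange(p)
            values[:, idx, idx] = 0.0
        self.values = values

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "AdjacencyStack":
        """Subject subset (no re-validation; slices stay symmetric)."""
        out = AdjacencyStack.__new__(AdjacencyStack)
        out.values = self.values[indices]
        out.subject_ids = self.subject_ids[indices]
        out.node_ids = self.node_ids
        return out


@dataclass
class CommunityPartition:
    """Node-to-community assignment and its p x K indicator matrix."""

    assignment: dict
    membership: np.ndarray  # p x K binary
    sizes: np.ndarray  # K community sizes
    community_labels: np.ndarray  # K labels, order of first appearance
    node_ids: np.ndarray  # p labels

    @property
    def n_nodes(self) -> int:
        return self.membership.shape[0]

    @property
    def n_communities(self) -> int:
        return self.membership.shape[1]

    def node_communities(self) -> np.ndarray:
        """Community index (0..K-1) for each node."""
        return np.argmax(self.membership, axis=1)


def build_membership(partition_table: dict, node_order) -> CommunityPartition:
    """Build the indicator matrix W from a node -> community-label map.

    Community columns are ordered by first appearance of each label when
    walking ``node_order``; this makes the construction deterministic.

    Raises
    ------
    UnassignedNodeError
        If a node in ``node_order`` is missing from the table.
    """
    node_order = list(node_order)
    labels: list = []
    for node in node_order:
        if node not in partition_table:
            raise UnassignedNodeError(f"unassigned node: {node!r}")
        lab = partition_table[node]
        if lab not in labels:
            labels.append(lab)
    p, K = len(node_order), len(labels)
    label_index = {lab: k for k, lab in enumerate(labels)}
    W = np.zeros((p, K), dtype=float)
    for j, node in enumerate(node_order):
        W[j, label_index[partition_table[node]]] = 1.0
    sizes = W.sum(axis=0).astype(int)
    return CommunityPartition(
        assignment={node: partition_table[node] for node in node_order},
        membership=W,
        sizes=sizes,
        community_labels=np.asarray(labels),
        node_ids=np.asarray(node_order),
    )


@dataclass
class CovariateTable:
    """n x q covariate matrix with optional centering/scaling state.

    ``standardize()`` computes column means and standard deviations from
    ``raw`` and returns a standardized copy; ``transform(center, scale)``
    applies externally supplied (training-set) statistics, which is the
    only leakage-free way to standardize held-out subjects.
    """

    raw: np.ndarray
    subject_ids: np.ndarray
    covariate_names: np.ndarray
    centered_scaled: np.ndarray | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __init__(self, raw, subject_ids=None, covariate_names=None):
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if not np.all(np.isfinite(raw)):
            raise ValueError("covariates contain non-finite values")
        n, q = raw.shape
        self.raw = raw
        self.subject_ids = np.asarray(
            subject_ids if subject_ids is not None else [f"s{i:04d}" for i in range(n)]
        )
        self.covariate_names = np.asarray(
            covariate_names if covariate_names is not None else [f"x{f}" for f in range(q)]
        )
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")
        if len(self.covariate_names) != q:
            raise ValueError("covariate_names length mismatch")
        self.centered_scaled = None
        self.center = None
        self.scale = None

    @property
    def n_subjects(self) -> int:
        return self.raw.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.raw.shape[1]

    @property
    def is_standardized(self) -> bool:
        return self.centered_scaled is not None

    def standardize(self) -> "CovariateTable":
        """Return a copy standardized with this table's own statistics."""
        center = self.raw.mean(axis=0)
        scale = self.raw.std(axis=0, ddof=0)
        if np.any(scale <= 0):
            bad = [str(n) for n, s in zip(self.covariate_names, scale) if s <= 0]
            raise ValueError(f"constant covariate column(s): {', '.join(bad)}")
        return self.transform(center, scale)

    def transform(self, center, scale) -> "CovariateTable":
        """Return a copy standardized with the given statistics."""
        center = np.asarray(center, dtype=float)
        scale = np.asarray(scale, dtype=float)
        if np.any(scale <= 0):
            raise ValueError("scale entries must be strictly positive")
        out = CovariateTable(self.raw, self.subject_ids, self.covariate_names)
        out.centered_scaled = (self.raw - center) / scale
        out.center = center
        out.scale = scale
        return out

    def subset(self, indices) -> "CovariateTable":
        out = CovariateTable(
            self.raw[indices], self.subject_ids[indices], self.covariate_names
        )
        if self.centered_scaled is not None:
            out.centered_scaled = self.centered_scaled[indices]
            out.center = self.center
            out.scale = self.scale
        return out


@dataclass
class FitDiagnostics:
    objective_trajectory: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    final_relative_change: float = np.inf
    trace_WtThetaW: float = 0.0


@dataclass
class MSNRModel:
    """A fitted model: Theta, the Gamma stack, penalties, and diagnostics.

    ``x_center``/``x_scale`` record the training-set covariate statistics;
    new subjects are standardized with them before prediction.
    """

    theta: np.ndarray  # p x p symmetric
    gammas: np.ndarray  # q x K x K, each slice symmetric
    lambda1: float
    lambda2: float
    partition: CommunityPartition
    x_center: np.ndarray
    x_scale: np.ndarray
    covariate_names: np.ndarray | None = None
    diagnostics: FitDiagnostics = field(default_factory=FitDiagnostics)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.gammas = np.asarray(self.gammas, dtype=float)
        if self.gammas.ndim == 2:
            self.gammas = self.gammas[None]
        _check_symmetric(self.theta, name="theta")
        for f, g in enumerate(self.gammas):
            _check_symmetric(g, name=f"gamma[{f}]")

    @property
    def n_covariates(self) -> int:
        return self.gammas.shape[0]

    def standardize_new(self, X: CovariateTable) -> np.ndarray:
        """Standardize raw covariates with the model's training statistics."""
        if X.is_standardized:
            return X.centered_scaled
        return (X.raw - self.x_center) / self.x_scale

    def predict_stack(self, X: CovariateTable) -> np.ndarray:
        """Predicted adjacency stack for a covariate table (raw scale ok)."""
        Xs = self.standardize_new(X)
        return predict_many(self, Xs)


def community_effect_matrix(gamma: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Expand a K x K block matrix to node level: W gamma W^T, diagonal zeroed."""
    M = W @ gamma @ W.T
    np.fill_diagonal(M, 0.0)
    return M


def predict(model: MSNRModel, x: np.ndarray) -> np.ndarray:
    """Forward map for one subject: Theta + sum_f x_f W Gamma^f W^T, zero diag.

    ``x`` must already be on the model's standardized covariate scale.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_covariates:
        raise ValueError(
            f"covariate vector length {x.shape[0]} != q={model.n_covariates}"
        )
    W = model.partition.membership
    G = np.tensordot(x, model.gammas, axes=1)  # K x K
    out = model.theta + W @ G @ W.T
    np.fill_diagonal(out, 0.0)
    return out


def predict_many(model: MSNRModel, Xs: np.ndarray) -> np.ndarray:
    """Vectorized predict for an n x q standardized covariate matrix."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    W = model.partition.membership
    G = np.tensordot(Xs, model.gammas, axes=([1], [0]))  # n x K x K
    out = model.theta[None] + np.einsum("jk,nkl,ml->njm", W, G, W)
    idx = np.arange(out.shape[1])
    out[:, idx, idx] = 0.0
    return out


def nuclear_norm_symmetric(M: np.ndarray) -> float:
    """Nuclear norm of a symmetric matrix: sum of |eigenvalues|.

    Exact for symmetric input (eigendecomposition instead of a general SVD).
    """
    _check_symmetric(M)
    return float(np.sum(np.abs(np.linalg.eigvalsh(M))))


def objective(
    model: MSNRModel,
    A: AdjacencyStack,
    X: CovariateTable,
) -> float:
    """Penalized objective: squared-Frobenius loss + nuclear + l1 penalties.

    The loss residual is ``A^i - Theta - sum_f x_if * zdiag(W Gamma^f W^T)``
    over all entries.  Since ``A^i`` and the community-effect term both have
    zero diagonals, the diagonal of ``Theta`` is compared against zero; this
    convention makes the solver's block updates exact minimizers.

    ``X`` must already be standardized.
    """
    if not X.is_standardized:
        raise ValueError("objective requires a standardized covariate table")
    Xs = X.centered_scaled
    if not (np.all(np.isfinite(A.values)) and np.all(np.isfinite(Xs))):
        raise ValueError("non-finite input")
    W = model.partition.membership
    G = np.tensordot(Xs, model.gammas, axes=([1], [0]))  # n x K x K
    pred = np.einsum("jk,nkl,ml->njm", W, G, W)
    idx = np.arange(pred.shape[1])
    pred[:, idx, idx] = 0.0  # community term excludes the diagonal
    pred += model.theta[None]
    loss = float(np.sum((A.values - pred) ** 2))
    pen1 = model.lambda1 * nuclear_norm_symmetric(model.theta)
    pen2 = model.lambda2 * float(np.sum(np.abs(model.gammas)))
    return loss + pen1 + pen2
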