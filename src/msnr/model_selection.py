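"""Train/validation split, cross-validated penalty tuning, and the
permutation significance test.

The tuning procedure mirrors the analysis design: hold out a validation
fraction, run five-fold cross-validation over a log-spaced (lambda1,
lambda2) grid on the training part, iteratively refine the grid around the
argmin, refit at the selected penalties, and score the held-out set with
the mean per-subject squared Frobenius prediction error.  Significance of
the whole model is assessed by permuting covariate rows (whole rows, so
the covariate covariance is preserved), re-tuning, and comparing
validation errors against the resulting null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import AdjacencyStack, CommunityPartition, CovariateTable
from .solver import SolverConfig, _prepare_fit, fit_msnr, lambda_max

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "PermutationResult",
    "prediction_error",
    "make_split",
    "standardize_train_test",
    "default_grids",
    "cross_validate",
    "refine_grid",
    "select_penalties",
    "permutation_pvalue",
    "permutation_test",
]


@dataclass
class CVResult:
    grid1: np.ndarray
    grid2: np.ndarray
    error_matrix: np.ndarray  # |grid1| x |grid2| mean CV errors
    fold_assignment: np.ndarray
    best: tuple[float, float]
    best_index: tuple[int, int]
    refinement_round: int = 0

    def to_dict(self) -> dict:
        return {
            "grid1": list(map(float, self.grid1)),
            "grid2": list(map(float, self.grid2)),
            "error_matrix": self.error_matrix.tolist(),
            "fold_assignment": self.fold_assignment.tolist(),
            "best_lambda1": float(self.best[0]),
            "best_lambda2": float(self.best[1]),
            "refinement_round": self.refinement_round,
        }


@dataclass
class PermutationResult:
    null_errors: np.ndarray
    observed_error: float
    p_value: float
    z_score: float
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "null_errors": list(map(float, self.null_errors)),
            "observed_error": float(self.observed_error),
            "p_value": float(self.p_value),
            "z_score": float(self.z_score),
            "seed": self.seed,
        }


def prediction_error(model, A_test: AdjacencyStack, X_test: CovariateTable) -> float:
    """Mean per-subject squared Frobenius error of predicted connectivity.

    Shared by all model families: any fitted object exposing
    ``predict_stack(X)`` (handling its own covariate scaling) works.
    """
    pred = model.predict_stack(X_test)
    if pred.shape != A_test.values.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != data shape {A_test.values.shape}"
        )
    return float(np.mean(np.sum((A_test.values - pred) ** 2, axis=(1, 2))))


def make_split(n: int, validation_fraction: float, seed) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/validation index split, reproducible per seed."""
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must lie in (0, 1)")
    n_val = int(round(validation_fraction * n))
    if n_val < 1 or n - n_val < 2:
        raise ValueError(f"n={n} too small for validation fraction {validation_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def standardize_train_test(
    X: CovariateTable, train_idx, test_idx
) -> tuple[CovariateTable, CovariateTable]:
    """Standardize both parts using statistics from the training rows only."""
    X_train = X.subset(train_idx).standardize()
    X_test = X.subset(test_idx).transform(X_train.center, X_train.scale)
    return X_train, X_test


def default_grids(
    A: AdjacencyStack,
    X: CovariateTable,
    partition: CommunityPartition,
    n_points: int = 10,
    lower_factor: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced penalty grids from lower_factor*lambda_max to lambda_max."""
    lam1_max, lam2_max = lambda_max(A, X, partition)
    g1 = np.geomspace(lower_factor * lam1_max, lam1_max, n_points)
    g2 = np.geomspace(lower_factor * lam2_max, lam2_max, n_points)
    return g1, g2


def _fold_assignment(n: int, n_folds: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, n_folds)):
        assignment[chunk] = fold
    return assignment


def _argmin_most_regularized(err: np.ndarray) -> tuple[int, int]:
    """Index of the minimal cell; ties break to largest lambda1 then lambda2."""
    best = np.min(err)
    ties = np.argwhere(err == best)
    order = np.lexsort((ties[:, 1], ties[:, 0]))  # row-major ascending
    i, j = ties[order[-1]]
    return int(i), int(j)


def cross_validate(
    A_train: AdjacencyStack,
    X_train: CovariateTable,
    partition: CommunityPartition,
    grid1,
    grid2,
    n_folds: int = 5,
    seed=0,
    config: SolverConfig | None = None,
    refinement_round: int = 0,
) -> CVResult:
    """K-fold CV of the prediction error over a penalty grid.

    For every fold, covariates are standardized with the in-fold training
    statistics only; the held-out fold reuses them (no leakage).  Ties at
    the argmin break toward the most regularized cell.
    """
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    if grid1.size == 0 or grid2.size == 0 or np.any(grid1 < 0) or np.any(grid2 < 0):
        raise ValueError("grids must be nonempty and nonnegative")
    n = A_train.n_subjects
    assignment = _fold_assignment(n, n_folds, seed)
    errors = np.zeros((n_folds, grid1.size, grid2.size))
    for fold in range(n_folds):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        if train_idx.size < 2:
            raise ValueError(f"fold {fold} leaves fewer than 2 training subjects")
        A_tr, A_te = A_train.subset(train_idx), A_train.subset(test_idx)
        X_tr, X_te = standardize_train_test(X_train, train_idx, test_idx)
        cache = _prepare_fit(A_tr, partition)  # shared across grid cells
        for i, lam1 in enumerate(grid1):
            for j, lam2 in enumerate(grid2):
                model = fit_msnr(A_tr, X_tr, partition, lam1, lam2, config, _cache=cache)
                errors[fold, i, j] = prediction_error(model, A_te, X_te)
    error_matrix = errors.mean(axis=0)
    bi, bj = _argmin_most_regularized(error_matrix)
    return CVResult(
        grid1=grid1,
        grid2=grid2,
        error_matrix=error_matrix,
        fold_assignment=assignment,
        best=(float(grid1[bi]), float(grid2[bj])),
        best_index=(bi, bj),
        refinement_round=refinement_round,
    )


def _refine_axis(grid: np.ndarray, idx: int, points: int) -> tuple[np.ndarray, bool]:
    """Log-spaced grid between the neighbors bracketing the argmin.

    At a grid edge the new grid extends one octave beyond that edge.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 1:
        return grid.copy(), False
    at_edge = idx in (0, grid.size - 1)
    lo = grid[idx - 1] if idx > 0 else grid[0] / 2.0
    hi = grid[idx + 1] if idx < grid.size - 1 else grid[-1] * 2.0
    lo = max(lo, np.finfo(float).tiny)
    return np.geomspace(lo, hi, points), at_edge


def refine_grid(result: CVResult, factor: float = 2.0, points: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """New grids bracketing the CV argmin in each penalty dimension."""
    bi, bj = result.best_index
    g1, edge1 = _refine_axis(result.grid1, bi, points)
    g2, edge2 = _refine_axis(result.grid2, bj, points)
    if edge1 or edge2:
        logger.warning(
            "CV argmin at grid boundary (lambda1 edge=%s, lambda2 edge=%s); "
            "refined grid extends one octave beyond",
            edge1,
            edge2,
        )
    return g1, g2


def select_penalties(
    A_train: AdjacencyStack,
    X_train: CovariateTable,
    partition: CommunityPartition,
    grid1=None,
    grid2=None,
    n_folds: int = 5,
    seed=0,
    config: SolverConfig | None = None,
    refinement_rounds: int = 2,
    grid_points: int = 10,
) -> list[CVResult]:
    """Coarse CV plus iterative grid refinement; returns one CVResult per round."""
    if grid1 is None or grid2 is None:
        grid1, grid2 = default_grids(A_train, X_train, partition, n_points=grid_points)
    results = [
        cross_validate(A_train, X_train, partition, grid1, grid2, n_folds, seed, config)
    ]
    for r in range(1, refinement_rounds + 1):
        grid1, grid2 = refine_grid(results[-1], points=grid_points)
        results.append(
            cross_validate(
                A_train, X_train, partition, grid1, grid2, n_folds, seed, config,
                refinement_round=r,
            )
        )
    return results


def permutation_pvalue(null_errors, observed: float) -> float:
    """Proportion of null prediction errors at or below the observed error."""
    null_errors = np.asarray(null_errors, dtype=float)
    if null_errors.size == 0:
        raise ValueError("empty null distribution")
    return float(np.sum(null_errors <= observed) / null_errors.size)


def _tuned_validation_error(
    A: AdjacencyStack,
    X: CovariateTable,
    partition: CommunityPartition,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    grid1,
    grid2,
    n_folds: int,
    cv_seed,
    config: SolverConfig | None,
    refinement_rounds: int,
    grid_points: int,
) -> tuple[float, CVResult]:
    A_tr, A_val = A.subset(train_idx), A.subset(val_idx)
    X_tr_raw, X_val_raw = X.subset(train_idx), X.subset(val_idx)
    results = select_penalties(
        A_tr, X_tr_raw, partition, grid1, grid2, n_folds, cv_seed, config,
        refinement_rounds=refinement_rounds, grid_points=grid_points,
    )
    lam1, lam2 = results[-1].best
    X_tr = X_tr_raw.standardize()
    model = fit_msnr(A_tr, X_tr, partition, lam1, lam2, config)
    err = prediction_error(model, A_val, X_val_raw)
    return err, results[-1]


def permutation_test(
    A: AdjacencyStack,
    X: CovariateTable,
    partition: CommunityPartition,
    split: tuple[np.ndarray, np.ndarray],
    n_perm: int = 1000,
    seed=0,
    grid1=None,
    grid2=None,
    n_folds: int = 5,
    config: SolverConfig | None = None,
    refinement_rounds: int = 0,
    grid_points: int = 10,
) -> PermutationResult:
    """Permutation test of the connectivity-covariate association.

    Whole rows of the covariate matrix are permuted across all subjects
    (train + validation) with the split held fixed; each permutation
    re-tunes the penalties by cross-validation and scores the validation
    set, building a null distribution of prediction errors.  By default
    permutations use the coarse grid without refinement (tractability; set
    ``refinement_rounds`` > 0 for the full procedure).  The observed error
    is computed by the identical pipeline on the unpermuted covariates.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    train_idx, val_idx = (np.asarray(split[0]), np.asarray(split[1]))
    n = A.n_subjects
    if grid1 is None or grid2 is None:
        X_tr_std = X.subset(train_idx).standardize()
        grid1, grid2 = default_grids(
            A.subset(train_idx), X_tr_std, partition, n_points=grid_points
        )
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31 - 1))

    observed, cv_last = _tuned_validation_error(
        A, X, partition, train_idx, val_idx, grid1, grid2,
        n_folds, cv_seed, config, refinement_rounds, grid_points,
    )
    null_errors = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        X_perm = CovariateTable(X.raw[perm], X.subject_ids, X.covariate_names)
        null_errors[b], _ = _tuned_validation_error(
            A, X_perm, partition, train_idx, val_idx, grid1, grid2,
            n_folds, cv_seed, config, refinement_rounds, grid_points,
        )
    p = permutation_pvalue(null_errors, observed)
    sd = float(np.std(null_errors))
    z = float((observed - null_errors.mean()) / sd) if sd > 0 else np.nan
    return PermutationResult(
        null_errors=null_errors,
        observed_error=observed,
        p_value=p,
        z_score=z,
        seed=seed if isinstance(seed, int) else None,
        extras={"cv_best": cv_last.best},
    )
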