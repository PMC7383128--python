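"""Post-fit interpretability summaries: sparsity of the community-effect
matrices, sign counts within vs between communities, and the correlation
of coefficients with inter-community distance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CommunityPartition

__all__ = [
    "NodeCoordinates",
    "sparsity_fraction",
    "count_signs",
    "community_distances",
    "coefficient_distance_correlation",
]


@dataclass
class NodeCoordinates:
    """3D node coordinates (mm, MNI-like space)."""

    coords: np.ndarray  # p x 3
    node_ids: np.ndarray

    def __init__(self, coords, node_ids=None):
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if coords.shape[1] != 3:
            raise ValueError(f"expected p x 3 coordinates, got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.coords = coords
        self.node_ids = np.asarray(
            node_ids if node_ids is not None else [f"n{j:04d}" for j in range(coords.shape[0])]
        )


def _unique_entries(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    iu = np.triu_indices(M.shape[0])
    return M[iu]


def sparsity_fraction(gammas: np.ndarray) -> np.ndarray:
    """Per covariate, the fraction of the K(K+1)/2 unique entries exactly 0."""
    gammas = np.asarray(gammas, dtype=float)
    if gammas.ndim == 2:
        gammas = gammas[None]
    return np.array([float(np.mean(_unique_entries(g) == 0.0)) for g in gammas])


def count_signs(gamma: np.ndarray) -> tuple[int, int, int, int]:
    """(within_pos, within_neg, between_pos, between_neg) sign counts.

    Within-community coefficients sit on the diagonal; between-community
    ones on the strict upper triangle (unique entries).
    """
    gamma = np.asarray(gamma, dtype=float)
    diag = np.diag(gamma)
    iu = np.triu_indices(gamma.shape[0], k=1)
    upper = gamma[iu]
    return (
        int(np.sum(diag > 0)),
        int(np.sum(diag < 0)),
        int(np.sum(upper > 0)),
        int(np.sum(upper < 0)),
    )


def community_distances(
    coords: NodeCoordinates,
    partition: CommunityPartition,
    method: str = "pairwise",
) -> np.ndarray:
    """K x K matrix of mean Euclidean distances between communities.

    ``pairwise`` (default) averages node-pair distances across the two
    communities (distinct pairs for k = k'); ``centroid`` uses the
    distance between community centroids.
    """
    if coords.coords.shape[0] != partition.n_nodes:
        raise ValueError("coordinate count does not match partition")
    K = partition.n_communities
    comm = partition.node_communities()
    out = np.zeros((K, K))
    if method == "centroid":
        centroids = np.stack([coords.coords[comm == k].mean(axis=0) for k in range(K)])
        diff = centroids[:, None, :] - centroids[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1))
    if method != "pairwise":
        raise ValueError(f"unknown method: {method}")
    D = np.sqrt(
        np.sum((coords.coords[:, None, :] - coords.coords[None, :, :]) ** 2, axis=-1)
    )
    for k in range(K):
        for kk in range(k, K):
            mask_k = comm == k
            mask_kk = comm == kk
            block = D[np.ix_(mask_k, mask_kk)]
            if k == kk:
                cnt = mask_k.sum() * (mask_k.sum() - 1)
                out[k, k] = block.sum() / cnt if cnt > 0 else 0.0
            else:
                out[k, kk] = out[kk, k] = block.mean()
    return out


def coefficient_distance_correlation(
    gamma: np.ndarray,
    distances: np.ndarray,
    include_zeros: bool = True,
) -> tuple[float, float]:
    """Pearson correlation of unique gamma entries with community distances.

    ``include_zeros=False`` restricts to entries where gamma is nonzero.
    Returns (r, two-sided p-value).
    """
    g = _unique_entries(gamma)
    dvec = _unique_entries(distances)
    if g.shape != dvec.shape:
        raise ValueError("gamma and distance matrices have different sizes")
    if not include_zeros:
        keep = g != 0.0
        g, dvec = g[keep], dvec[keep]
    if g.size < 3 or np.std(g) == 0.0 or np.std(dvec) == 0.0:
        raise ValueError("correlation undefined: zero variance or too few entries")
    r, p = stats.pearsonr(g, dvec)
    return float(r), float(p)
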