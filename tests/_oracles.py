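"""Independent reference implementations used only by the test suite.

Everything here is written from the problem statement, not from the
package internals: naive loops, entry-wise sums, and a generic proximal
gradient (FISTA) minimizer of the full convex objective.  Deliberately
slow and simple.
"""

from __future__ import annotations

import numpy as np


def reference_objective(Avals, Xs, W, theta, gammas, lam1, lam2) -> float:
    """Entry-wise evaluation of the penalized objective, loops and all."""
    n, p, _ = Avals.shape
    q = Xs.shape[1]
    total = 0.0
    for i in range(n):
        effect = np.zeros((p, p))
        for f in range(q):
            M = W @ gammas[f] @ W.T
            for j in range(p):
                M[j, j] = 0.0
            effect += Xs[i, f] * M
        resid = Avals[i] - theta - effect
        for j in range(p):
            for jj in range(p):
                total += resid[j, jj] ** 2
    sv = np.linalg.svd(theta, compute_uv=False)
    total += lam1 * float(np.sum(sv))
    total += lam2 * float(np.sum(np.abs(gammas)))
    return total


def _fast_objective(Avals, Xs, W, theta, gammas, lam1, lam2) -> float:
    """Vectorized version of reference_objective for use inside FISTA."""
    effect = np.einsum("jk,fkl,ml->fjm", W, gammas, W)
    idx = np.arange(W.shape[0])
    effect[:, idx, idx] = 0.0
    pred = theta[None] + np.tensordot(Xs, effect, axes=([1], [0]))
    loss = float(np.sum((Avals - pred) ** 2))
    sv = np.linalg.svd(theta, compute_uv=False)
    return loss + lam1 * float(np.sum(sv)) + lam2 * float(np.sum(np.abs(gammas)))


def _smooth_grad(Avals, Xs, W, theta, gammas):
    effect = np.einsum("jk,fkl,ml->fjm", W, gammas, W)
    idx = np.arange(W.shape[0])
    effect[:, idx, idx] = 0.0
    E = Avals - theta[None] - np.tensordot(Xs, effect, axes=([1], [0]))
    g_theta = -2.0 * E.sum(axis=0)
    E_offdiag = E.copy()
    E_offdiag[:, idx, idx] = 0.0
    inner = np.einsum("jk,njm,ml->nkl", W, E_offdiag, W)
    g_gammas = -2.0 * np.tensordot(Xs.T, inner, axes=([1], [0]))
    return g_theta, g_gammas


def _smooth_value(Avals, Xs, W, theta, gammas) -> float:
    effect = np.einsum("jk,fkl,ml->fjm", W, gammas, W)
    idx = np.arange(W.shape[0])
    effect[:, idx, idx] = 0.0
    pred = theta[None] + np.tensordot(Xs, effect, axes=([1], [0]))
    return float(np.sum((Avals - pred) ** 2))


def _prox(theta, gammas, t, lam1, lam2):
    theta = 0.5 * (theta + theta.T)
    d, U = np.linalg.eigh(theta)
    d = np.sign(d) * np.maximum(np.abs(d) - t * lam1, 0.0)
    theta_new = (U * d) @ U.T
    gammas_new = np.sign(gammas) * np.maximum(np.abs(gammas) - t * lam2, 0.0)
    return 0.5 * (theta_new + theta_new.T), gammas_new


def fista_minimize(
    Avals,
    Xs,
    W,
    lam1,
    lam2,
    max_iter: int = 50000,
    rel_tol: float = 1e-12,
    patience: int = 200,
):
    """Accelerated proximal gradient on (theta, gammas) with backtracking.

    Returns (theta, gammas, objective) at the best iterate found.
    """
    Avals = np.asarray(Avals, dtype=float)
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    p = Avals.shape[1]
    K = W.shape[1]
    q = Xs.shape[1]
    theta = np.zeros((p, p))
    gammas = np.zeros((q, K, K))
    y_t, y_g = theta.copy(), gammas.copy()
    t_step = 1.0 / (2.0 * Avals.shape[0])
    momentum = 1.0
    best = _fast_objective(Avals, Xs, W, theta, gammas, lam1, lam2)
    best_theta, best_gammas = theta.copy(), gammas.copy()
    stall = 0
    for _ in range(max_iter):
        g_val = _smooth_value(Avals, Xs, W, y_t, y_g)
        g_t, g_g = _smooth_grad(Avals, Xs, W, y_t, y_g)
        while True:
            cand_t, cand_g = _prox(y_t - t_step * g_t, y_g - t_step * g_g, t_step, lam1, lam2)
            dt_, dg_ = cand_t - y_t, cand_g - y_g
            lhs = _smooth_value(Avals, Xs, W, cand_t, cand_g)
            rhs = (
                g_val
                + float(np.sum(g_t * dt_) + np.sum(g_g * dg_))
                + (float(np.sum(dt_**2)) + float(np.sum(dg_**2))) / (2.0 * t_step)
            )
            if lhs <= rhs + 1e-12 * max(abs(rhs), 1.0):
                break
            t_step *= 0.5
        new_momentum = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * momentum**2))
        accel = (momentum - 1.0) / new_momentum
        y_t = cand_t + accel * (cand_t - theta)
        y_g = cand_g + accel * (cand_g - gammas)
        theta, gammas = cand_t, cand_g
        momentum = new_momentum
        obj = _fast_objective(Avals, Xs, W, theta, gammas, lam1, lam2)
        if obj < best - rel_tol * max(1.0, best):
            best = obj
            best_theta, best_gammas = theta.copy(), gammas.copy()
            stall = 0
        else:
            stall += 1
            if obj > best:  # restart momentum on non-monotone step
                y_t, y_g = best_theta.copy(), best_gammas.copy()
                theta, gammas = best_theta.copy(), best_gammas.copy()
                momentum = 1.0
            if stall >= patience:
                break
    return best_theta, best_gammas, best


def brute_force_block_means(values, node_communities, K):
    """Per-subject block means by explicit index-pair loops."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    n = values.shape[0]
    pairs = [(k, kk) for k in range(K) for kk in range(k, K)]
    means = np.zeros((n, len(pairs)))
    counts = np.zeros(len(pairs))
    for b, (k, kk) in enumerate(pairs):
        idx_k = [j for j, cj in enumerate(node_communities) if cj == k]
        idx_kk = [j for j, cj in enumerate(node_communities) if cj == kk]
        for i in range(n):
            tot, cnt = 0.0, 0
            for j in idx_k:
                for jj in idx_kk:
                    if j == jj:
                        continue
                    tot += values[i, j, jj]
                    cnt += 1
                    if k != kk:
                        tot += values[i, jj, j]
                        cnt += 1
            counts[b] = cnt / (2 if k != kk else 1)
            means[i, b] = tot / cnt if cnt else 0.0
    return means, counts, pairs


def brute_force_bh(p_values, q_level):
    """Benjamini-Hochberg step-up straight from its definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q_level / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def normal_equation_ols(y, design):
    """(X^T X)^{-1} X^T y, written out."""
    design = np.asarray(design, dtype=float)
    return np.linalg.solve(design.T @ design, design.T @ np.asarray(y, dtype=float))
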