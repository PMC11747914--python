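"""Similarity Network Fusion: merge per-measure participant affinities.

Cross-diffusion between views: each view's full transition matrix is updated
through its own sparse K-nearest-neighbour kernel applied to the average of
the *other* views' transition matrices.  After a fixed number of iterations
the symmetrized mean of the views is returned.  Each update renormalizes and
symmetrizes to control numerical drift.
"""

from __future__ import annotations

import numpy as np


def full_normalize(w: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix: off-diagonal mass 1/2, diagonal 1/2."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if np.any(row <= 0):
        i = int(np.argmin(row))
        raise ValueError(f"row {i} has no off-diagonal mass; cannot normalize")
    p = off / (2.0 * row[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def knn_kernel(w: np.ndarray, K: int) -> np.ndarray:
    """Sparse kernel keeping each row's K largest off-diagonal affinities, row-normalized.

    Ties in the K-th affinity break toward the lower participant index.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if not (1 <= K < n):
        raise ValueError("K must satisfy 1 <= K < n")
    off = w.copy()
    np.fill_diagonal(off, -np.inf)
    # stable ordering: sort by (-affinity, index)
    order = np.argsort(-off, axis=1, kind="stable")[:, :K]
    s = np.zeros_like(w)
    rows = np.repeat(np.arange(n), K)
    cols = order.ravel()
    s[rows, cols] = w[rows, cols]
    sums = s.sum(axis=1, keepdims=True)
    sums[sums <= 0] = 1.0
    return s / sums


def snf_fuse(matrices, K: int, t_max: int = 20, return_trace: bool = False) -> np.ndarray:
    """Fuse two or more similarity matrices into one network.

    Iterates ``P_v <- S_v @ mean(P_u, u != v) @ S_v.T`` followed by
    symmetrization with diagonal regularization; the result is the
    symmetrized mean of the views after ``t_max`` iterations.
    """
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if len(mats) < 2:
        raise ValueError("need at least 2 matrices to fuse")
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("all similarity matrices must share the participant set")

    ps = [full_normalize(m) for m in mats]
    ss = [knn_kernel(m, K) for m in mats]
    trace = []
    for _ in range(t_max):
        means = []
        total = np.sum(ps, axis=0)
        for v in range(len(ps)):
            means.append((total - ps[v]) / (len(ps) - 1))
        new_ps = []
        for v in range(len(ps)):
            p = ss[v] @ means[v] @ ss[v].T
            p = (p + p.T) / 2 + np.eye(n)  # symmetrize + diagonal regularization
            new_ps.append(full_normalize(p))
        if return_trace:
            trace.append(max(np.abs(new_ps[v] - ps[v]).max() for v in range(len(ps))))
        ps = new_ps

    fused = np.mean(ps, axis=0)
    fused = (fused + fused.T) / 2
    if return_trace:
        return fused, trace
    return fused
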