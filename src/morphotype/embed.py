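"""Joint embedding of the fused participant network and regional features,
k-means clustering, parameter-grid consensus, and cluster-number selection.

The embedder is a two-layer graph-convolutional autoencoder: participants are
nodes of the fused similarity network, node features are the z-scored
regional measures of all four structural measures concatenated, and the
network is trained to reconstruct both the (thresholded) adjacency through an
inner-product decoder and the features through a linear decoder.  It is
implemented directly on numpy arrays with analytically derived gradients and
Adam updates, which keeps training bit-reproducible from a single seed.

Cluster stability follows standard consensus clustering: k-means solutions
are collected over a grid of fusion parameters (scaling factor mu, number of
neighbours K) and seeds, co-assignment frequencies form the consensus matrix,
and final labels come from average-linkage hierarchical clustering of the
consensus dissimilarity.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score

from .fusion import snf_fuse
from .similarity import scaled_exponential_kernel

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    coords: np.ndarray       # (N, d)
    seed: int
    epochs: int
    loss_trace: np.ndarray


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    consensus: np.ndarray    # (N, N) co-assignment frequencies
    n_runs: int
    grid: dict = field(default_factory=dict)


@dataclass
class QualityProfile:
    ks: list
    davies_bouldin: list
    silhouette: list
    calinski_harabasz: list
    selected_k: int | None = None
    selection_rule: str = "majority vote (DB min, silhouette max, CH max); tie -> silhouette"


def feature_matrix(tables: dict) -> tuple[np.ndarray, list]:
    """Concatenate and z-score regional measures across the four tables.

    Returns the (N, sum R_v) feature matrix and the column names.  All tables
    must share the participant index; constant regions are rejected because
    they cannot be z-scored.
    """
    names = list(tables)
    base = tables[names[0]].index
    for name in names[1:]:
        if not tables[name].index.equals(base):
            missing = set(base).symmetric_difference(tables[name].index)
            raise ValueError(f"participant sets differ across measures: {sorted(missing)[:5]}")
    blocks, columns = [], []
    for name in names:
        values = tables[name].to_numpy(dtype=float)
        sd = values.std(axis=0, ddof=0)
        const = np.flatnonzero(sd < 1e-12)
        if const.size:
            raise ValueError(f"region {tables[name].columns[const[0]]!r} is constant")
        blocks.append((values - values.mean(axis=0)) / sd)
        columns.extend(tables[name].columns)
    return np.hstack(blocks), columns


def _sym_normalize(adj: np.ndarray) -> np.ndarray:
    deg = adj.sum(axis=1)
    deg = np.maximum(deg, 1e-12)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return adj * np.outer(inv_sqrt, inv_sqrt)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def gnn_embed(
    fused: np.ndarray,
    features: np.ndarray,
    d: int = 32,
    epochs: int = 150,
    seed: int = 0,
    hidden: int = 64,
    lr: float = 0.01,
    adj_weight: float = 0.1,
    target_k: int = 20,
) -> Embedding:
    """Train the graph-convolutional autoencoder and return node coordinates.

    Encoder: Z = A_hat . relu(A_hat X W1 + b1) W2 + b2 with the
    symmetric-normalized fused matrix A_hat.  Loss = ``adj_weight`` x binary
    cross-entropy of the inner-product adjacency decoder against the fused
    network's symmetrized ``target_k``-nearest-neighbour graph, plus mean
    squared error of a linear feature decoder.  The adjacency term is
    down-weighted because the inner-product decoder otherwise dominates the
    embedding geometry and drowns the regional-feature signal.  Deterministic
    given the seed.
    """
    a = np.asarray(fused, dtype=float)
    x = np.asarray(features, dtype=float)
    n = a.shape[0]
    if x.shape[0] != n:
        raise ValueError("fused matrix and features must share participant ordering")
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")

    a_hat = _sym_normalize(a)
    off = a.copy()
    np.fill_diagonal(off, -np.inf)
    kk = min(target_k, n - 1)
    thresh = np.sort(off, axis=1)[:, -kk][:, None]
    target = (off >= thresh).astype(float)
    target = np.maximum(target, target.T)  # symmetrize by OR
    np.fill_diagonal(target, 1.0)

    rng = np.random.default_rng(seed)
    f = x.shape[1]
    w1 = _glorot(rng, f, hidden)
    b1 = np.zeros(hidden)
    w2 = _glorot(rng, hidden, d)
    b2 = np.zeros(d)
    w3 = _glorot(rng, d, f)
    b3 = np.zeros(f)

    params = [w1, b1, w2, b2, w3, b3]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8

    ax = a_hat @ x
    losses = np.empty(epochs)
    for epoch in range(epochs):
        h_pre = ax @ w1 + b1
        h = np.maximum(h_pre, 0.0)
        ah = a_hat @ h
        z = ah @ w2 + b2

        # inner-product adjacency decoder
        logits = z @ z.T
        p = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
        bce = -(target * np.log(p + 1e-12) + (1 - target) * np.log(1 - p + 1e-12)).mean()

        x_hat = z @ w3 + b3
        mse = ((x_hat - x) ** 2).mean()
        loss = adj_weight * bce + mse
        losses[epoch] = loss
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")

        g_s = adj_weight * (p - target) / (n * n)
        dz = (g_s + g_s.T) @ z
        dxhat = 2.0 * (x_hat - x) / x_hat.size
        dw3 = z.T @ dxhat
        db3 = dxhat.sum(axis=0)
        dz += dxhat @ w3.T

        dw2 = ah.T @ dz
        db2 = dz.sum(axis=0)
        dh = a_hat @ (dz @ w2.T)
        dh_pre = dh * (h_pre > 0)
        dw1 = ax.T @ dh_pre
        db1 = dh_pre.sum(axis=0)

        grads = [dw1, db1, dw2, db2, dw3, db3]
        t = epoch + 1
        for p_i, g_i, m_i, v_i in zip(params, grads, m_t, v_t):
            m_i *= beta1
            m_i += (1 - beta1) * g_i
            v_i *= beta2
            v_i += (1 - beta2) * g_i**2
            m_hat = m_i / (1 - beta1**t)
            v_hat = v_i / (1 - beta2**t)
            p_i -= lr * m_hat / (np.sqrt(v_hat) + eps_adam)

    h = np.maximum(ax @ w1 + b1, 0.0)
    z = a_hat @ h @ w2 + b2
    return Embedding(coords=z, seed=seed, epochs=epochs, loss_trace=losses)


def kmeans_cluster(embedding: np.ndarray, k: int, n_init: int = 10, seed: int = 0) -> np.ndarray:
    """Best-of-n_init k-means labels on embedding coordinates."""
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    if k >= coords.shape[0]:
        raise ValueError("k must be smaller than the number of participants")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(coords)


def consensus_cluster(
    distances: list,
    features: np.ndarray,
    k: int,
    mu_grid=(0.3, 0.5, 0.8),
    k_neighbor_grid=(10, 20, 30),
    seeds=(0, 1, 2, 3),
    budget: int = 100,
    *,
    epochs: int = 150,
    embed_dim: int = 32,
    hidden: int = 64,
    snf_iterations: int = 20,
    kmeans_n_init: int = 4,
    cache: dict | None = None,
) -> ClusterSolution:
    """Consensus k-means over a grid of fusion parameters and seeds.

    Each run draws a (mu, K, seed) configuration from the grid (cycled to
    ``budget`` runs), re-fuses the per-measure distance matrices with that
    kernel, embeds the fused network (cached per configuration), and runs
    k-means with a run-specific seed.  The consensus matrix holds
    co-assignment fractions; final labels cut an average-linkage tree of
    1 - consensus at k.  Runs that fail are logged and excluded; more than
    10% failures is an error.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    configs = list(itertools.product(mu_grid, k_neighbor_grid, seeds))
    if not configs:
        raise ValueError("parameter grid is empty")
    n = distances[0].shape[0]
    if cache is None:
        cache = {}

    counts = np.zeros((n, n))
    co = np.zeros((n, n))
    n_fail = 0
    n_ok = 0
    for run in range(budget):
        mu, kk, seed = configs[run % len(configs)]
        kk_eff = min(int(kk), n - 1)
        key = (mu, kk_eff, seed)
        try:
            if key not in cache:
                mats = [scaled_exponential_kernel(dm, mu, kk_eff) for dm in distances]
                fused = snf_fuse(mats, K=kk_eff, t_max=snf_iterations)
                emb = gnn_embed(fused, features, d=embed_dim, epochs=epochs, seed=seed, hidden=hidden)
                cache[key] = emb
            labels = kmeans_cluster(cache[key], k, n_init=kmeans_n_init, seed=1_000_003 * seed + run)
        except Exception as exc:  # noqa: BLE001 - failing runs are excluded by contract
            logger.warning("consensus run %d (mu=%s, K=%s, seed=%s) failed: %s", run, mu, kk, seed, exc)
            n_fail += 1
            continue
        same = labels[:, None] == labels[None, :]
        co += same
        counts += 1.0
        n_ok += 1

    if n_fail > 0.1 * budget:
        raise RuntimeError(f"{n_fail}/{budget} consensus runs failed")
    consensus = co / np.maximum(counts, 1.0)
    np.fill_diagonal(consensus, 1.0)

    cond = squareform(1.0 - consensus, checks=False)
    tree = linkage(cond, method="average")
    final = fcluster(tree, t=k, criterion="maxclust") - 1
    return ClusterSolution(
        k=k,
        labels=final,
        consensus=consensus,
        n_runs=n_ok,
        grid={"mu": list(mu_grid), "K": list(k_neighbor_grid), "seeds": list(seeds), "budget": budget},
    )


def quality_scores(embedding, labels) -> dict:
    """Davies-Bouldin (lower better), silhouette and Calinski-Harabasz (higher better).

    Silhouette is recorded as missing when any cluster is a singleton.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    labels = np.asarray(labels)
    uniq, sizes = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters for quality indices")
    sil = None
    if sizes.min() >= 2:
        sil = float(silhouette_score(coords, labels))
    else:
        warnings.warn("singleton cluster: silhouette undefined, recorded as missing", stacklevel=2)
    return {
        "davies_bouldin": float(davies_bouldin_score(coords, labels)),
        "silhouette": sil,
        "calinski_harabasz": float(calinski_harabasz_score(coords, labels)),
    }


def select_k(profile: QualityProfile) -> int:
    """Majority vote of the three indices; a three-way split defers to silhouette."""
    ks = list(profile.ks)
    votes = []
    db = [v for v in profile.davies_bouldin]
    votes.append(ks[int(np.argmin(db))])
    sil_pairs = [(k, s) for k, s in zip(ks, profile.silhouette) if s is not None]
    sil_winner = max(sil_pairs, key=lambda p: p[1])[0] if sil_pairs else None
    if sil_winner is not None:
        votes.append(sil_winner)
    votes.append(ks[int(np.argmax(profile.calinski_harabasz))])
    vals, counts = np.unique(votes, return_counts=True)
    best = vals[counts == counts.max()]
    if best.size == 1:
        selected = int(best[0])
    else:
        selected = int(sil_winner if sil_winner is not None else best[0])
    profile.selected_k = selected
    return selected


def cluster_sweep(
    distances: list,
    features: np.ndarray,
    k_range=(2, 3, 4, 5, 6),
    *,
    budget_per_k: int = 100,
    mu_grid=(0.3, 0.5, 0.8),
    k_neighbor_grid=(10, 20, 30),
    seeds=(0, 1, 2, 3),
    epochs: int = 150,
    embed_dim: int = 32,
    hidden: int = 64,
    snf_iterations: int = 20,
    kmeans_n_init: int = 4,
):
    """Consensus solutions for every candidate k plus the quality profile.

    Fusion/embedding results are cached across k (they do not depend on k),
    so the sweep mostly re-runs k-means.  Quality indices are evaluated on a
    reference embedding (middle grid configuration, first seed) with each k's
    consensus labels.
    """
    cache: dict = {}
    solutions = {}
    for k in k_range:
        solutions[k] = consensus_cluster(
            distances,
            features,
            k,
            mu_grid=mu_grid,
            k_neighbor_grid=k_neighbor_grid,
            seeds=seeds,
            budget=budget_per_k,
            epochs=epochs,
            embed_dim=embed_dim,
            hidden=hidden,
            snf_iterations=snf_iterations,
            kmeans_n_init=kmeans_n_init,
            cache=cache,
        )
    n = distances[0].shape[0]
    ref_key = (
        mu_grid[len(mu_grid) // 2],
        min(int(k_neighbor_grid[len(k_neighbor_grid) // 2]), n - 1),
        seeds[0],
    )
    if ref_key not in cache:  # small budgets may not reach the middle configuration
        ref_key = next(iter(cache))
    ref_emb = cache[ref_key]
    profile = QualityProfile(ks=[], davies_bouldin=[], silhouette=[], calinski_harabasz=[])
    for k in k_range:
        scores = quality_scores(ref_emb, solutions[k].labels)
        profile.ks.append(k)
        profile.davies_bouldin.append(scores["davies_bouldin"])
        profile.silhouette.append(scores["silhouette"])
        profile.calinski_harabasz.append(scores["calinski_harabasz"])
    selected = select_k(profile)
    return solutions, profile, selected, ref_emb


def labels_frame(participant_ids, labels) -> pd.DataFrame:
    return pd.DataFrame({"participant_id": list(participant_ids), "cluster": np.asarray(labels)})
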