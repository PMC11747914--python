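"""Feature assembly, graph autoencoder, k-means, consensus, quality indices."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from morphotype.embed import (
    Embedding,
    consensus_cluster,
    feature_matrix,
    gnn_embed,
    kmeans_cluster,
    quality_scores,
    select_k,
    QualityProfile,
)


def _block_problem(rng, n=60, sep=6.0):
    """Two well-separated similarity blocks with block-distinct features."""
    labels = np.repeat([0, 1], n // 2)
    same = labels[:, None] == labels[None, :]
    fused = np.where(same, 0.9, 0.05) + 0.01 * rng.standard_normal((n, n))
    fused = np.clip((fused + fused.T) / 2, 0.01, 1.0)
    np.fill_diagonal(fused, 1.0)
    feats = rng.standard_normal((n, 8))
    feats[labels == 1] += sep / np.sqrt(8)
    feats = (feats - feats.mean(0)) / feats.std(0)
    return fused, feats, labels


class TestFeatureMatrix:
    def _tables(self, rng, n=10):
        ids = pd.Index([f"P{i}" for i in range(n)], name="participant_id")
        t1 = pd.DataFrame(rng.standard_normal((n, 3)) + 5, index=ids, columns=list("abc"))
        t2 = pd.DataFrame(rng.standard_normal((n, 3)) * 2, index=ids, columns=list("xyz"))
        return {"m1": t1, "m2": t2}

    def test_concatenates_and_zscores(self, rng):
        feats, cols = feature_matrix(self._tables(rng))
        assert feats.shape == (10, 6)
        assert cols == list("abcxyz")
        np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(feats.std(axis=0), 1.0, atol=1e-10)

    def test_constant_region_rejected_by_name(self, rng):
        tables = self._tables(rng)
        tables["m2"]["y"] = 3.0
        with pytest.raises(ValueError, match="y"):
            feature_matrix(tables)

    def test_participant_mismatch_rejected(self, rng):
        tables = self._tables(rng)
        tables["m2"] = tables["m2"].iloc[:-1]
        with pytest.raises(ValueError, match="participant"):
            feature_matrix(tables)


class TestGnnEmbed:
    def test_deterministic_given_seed(self, rng):
        fused, feats, _ = _block_problem(rng, n=30)
        a = gnn_embed(fused, feats, d=8, epochs=30, seed=5)
        b = gnn_embed(fused, feats, d=8, epochs=30, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)

    def test_duplicated_participants_get_equal_embeddings(self, rng):
        """Two participants with identical similarities and features embed identically."""
        fused, feats, _ = _block_problem(rng, n=30)
        fused[1] = fused[0]
        fused[:, 1] = fused[:, 0]
        fused[1, 1] = fused[0, 0]
        fused[0, 1] = fused[1, 0] = fused[0, 0]
        feats[1] = feats[0]
        emb = gnn_embed(fused, feats, d=8, epochs=50, seed=0)
        assert np.abs(emb.coords[0] - emb.coords[1]).max() < 1e-4

    def test_planted_blocks_recovered_perfectly(self, rng):
        fused, feats, labels = _block_problem(rng, n=100)
        emb = gnn_embed(fused, feats, d=16, epochs=100, seed=0)
        pred = kmeans_cluster(emb, 2, seed=0)
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_loss_trace_settles(self, rng):
        fused, feats, _ = _block_problem(rng, n=40)
        emb = gnn_embed(fused, feats, d=8, epochs=100, seed=1)
        tail = emb.loss_trace[-10:]
        assert tail.max() - tail.min() < 0.1 * abs(emb.loss_trace[0])
        assert np.isfinite(emb.loss_trace).all()

    def test_mismatched_inputs_rejected(self, rng):
        fused, feats, _ = _block_problem(rng, n=20)
        with pytest.raises(ValueError):
            gnn_embed(fused, feats[:-1], d=4, epochs=5)


class TestKmeans:
    def test_two_point_masses_perfectly_separated(self):
        coords = np.array([[0.0, 0], [0, 0], [10, 10], [10, 10]])
        labels = kmeans_cluster(coords, 2, seed=0)
        assert labels[0] == labels[1] and labels[2] == labels[3] and labels[0] != labels[2]

    def test_k1_single_label(self, rng):
        labels = kmeans_cluster(rng.standard_normal((10, 2)), 1, seed=0)
        assert np.unique(labels).size == 1

    def test_matches_exhaustive_two_partition_oracle(self, rng):
        """Global optimum by brute force over all 2-partitions, n <= 12."""
        coords = rng.standard_normal((10, 2))
        best_inertia, best = np.inf, None
        for assignment in itertools.product([0, 1], repeat=10):
            a = np.array(assignment)
            if a.min() == a.max():
                continue
            inertia = sum(
                ((coords[a == g] - coords[a == g].mean(0)) ** 2).sum() for g in (0, 1)
            )
            if inertia < best_inertia:
                best_inertia, best = inertia, a
        labels = kmeans_cluster(coords, 2, n_init=20, seed=0)
        assert adjusted_rand_score(best, labels) == 1.0

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.standard_normal((5, 2)), 5)


class TestConsensus:
    def _distance_views(self, rng, labels):
        views = []
        for _ in range(2):
            x = rng.standard_normal((labels.size, 3))
            x[labels == 1] += 4.0
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            views.append(d)
        return views

    def test_consensus_matrix_contract(self, rng):
        labels = np.repeat([0, 1], 15)
        dists = self._distance_views(rng, labels)
        feats = rng.standard_normal((30, 4))
        sol = consensus_cluster(dists, feats, 2, mu_grid=(0.5,), k_neighbor_grid=(5,),
                                seeds=(0,), budget=10, epochs=20, embed_dim=4, hidden=8)
        c = sol.consensus
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert np.all((c >= 0) & (c <= 1))
        assert np.unique(sol.labels).size == 2

    def test_identical_runs_give_binary_consensus(self, rng):
        """All runs agree -> co-assignment fractions are exactly 0 or 1 and the
        final labels reproduce them."""
        labels = np.repeat([0, 1], 20)
        dists = self._distance_views(rng, labels)
        feats = rng.standard_normal((40, 4))
        feats[labels == 1] += 5.0
        sol = consensus_cluster(dists, feats, 2, mu_grid=(0.5,), k_neighbor_grid=(8,),
                                seeds=(0,), budget=8, epochs=40, embed_dim=4, hidden=8)
        assert set(np.round(sol.consensus, 10).ravel()) <= {0.0, 1.0}
        assert adjusted_rand_score(sol.labels, labels) == 1.0

    def test_planted_clusters_recovered(self, rng):
        labels = np.repeat([0, 1], 25)
        dists = self._distance_views(rng, labels)
        feats = rng.standard_normal((50, 4))
        feats[labels == 1] += 4.0
        sol = consensus_cluster(dists, feats, 2, mu_grid=(0.3, 0.8), k_neighbor_grid=(5, 10),
                                seeds=(0, 1), budget=40, epochs=40, embed_dim=4, hidden=8)
        assert adjusted_rand_score(sol.labels, labels) >= 0.9

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            consensus_cluster([np.zeros((4, 4))], np.zeros((4, 2)), 2,
                              mu_grid=(), k_neighbor_grid=(), seeds=(), budget=5)


class TestQuality:
    def test_far_blobs_select_two_clusters(self, rng):
        coords = rng.standard_normal((80, 2))
        coords[40:] += 12.0
        profile = QualityProfile(ks=[], davies_bouldin=[], silhouette=[], calinski_harabasz=[])
        for k in range(2, 7):
            labels = kmeans_cluster(coords, k, seed=0)
            s = quality_scores(coords, labels)
            profile.ks.append(k)
            profile.davies_bouldin.append(s["davies_bouldin"])
            profile.silhouette.append(s["silhouette"])
            profile.calinski_harabasz.append(s["calinski_harabasz"])
        assert profile.silhouette[0] > 0.9
        assert select_k(profile) == 2

    def test_single_blob_split_has_near_zero_silhouette(self, rng):
        coords = rng.standard_normal((100, 2))
        labels = kmeans_cluster(coords, 2, seed=0)
        s = quality_scores(coords, labels)
        assert s["silhouette"] < 0.5

    def test_hand_computed_four_point_configuration(self):
        """2 clusters of 2 points each; all three indices by hand arithmetic.

        Points (0,0),(0,1) in cluster 0 and (4,0),(4,1) in cluster 1.
        """
        coords = np.array([[0.0, 0], [0, 1], [4, 0], [4, 1]])
        labels = np.array([0, 0, 1, 1])
        s = quality_scores(coords, labels)
        # silhouette: a=1, b=mean(sqrt(16), sqrt(17)) for each point
        b = (4 + np.sqrt(17)) / 2
        sil = (b - 1) / b
        assert s["silhouette"] == pytest.approx(sil, abs=1e-10)
        # Davies-Bouldin: sigma_i = mean distance to centroid = 0.5; d(c_i,c_j)=4
        assert s["davies_bouldin"] == pytest.approx((0.5 + 0.5) / 4, abs=1e-10)
        # Calinski-Harabasz: between = 4*(2^2)=16, within = 4*(0.5^2)=1
        assert s["calinski_harabasz"] == pytest.approx((16 / 1) * (4 - 2) / (2 - 1), abs=1e-10)

    def test_quality_invariant_to_label_renaming(self, rng):
        coords = rng.standard_normal((30, 3))
        labels = rng.integers(0, 3, 30)
        s1 = quality_scores(coords, labels)
        s2 = quality_scores(coords, 2 - labels)
        for key in s1:
            assert s1[key] == pytest.approx(s2[key], abs=1e-12)

    def test_singleton_cluster_silhouette_missing(self):
        coords = np.array([[0.0, 0], [0, 1], [5, 5]])
        with pytest.warns(UserWarning, match="singleton"):
            s = quality_scores(coords, np.array([0, 0, 1]))
        assert s["silhouette"] is None
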