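import numpy as np
import pandas as pd
import pytest

from celltracks import (
    ClusterConfig,
    EmbeddingConfig,
    build_feature_matrix,
    cluster_profile,
    cluster_tracks,
    compute_track_metrics,
    embed,
    exemplar_tracks,
    fingerprint,
)
from conftest import make_dataset


def blob_matrix(n_per=100, sep=10.0, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_per, dim)), rng.normal(sep, 1, (n_per, dim))])
    ids = pd.Index([f"t::{i}" for i in range(2 * n_per)], name="unique_track_id")
    truth = np.array([0] * n_per + [1] * n_per)
    return X, ids, truth


class TestFeatureMatrix:
    def test_columns_are_z_scored(self, two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        X, ids = build_feature_matrix(ds, ["Mean Speed", "Directionality"])
        assert np.abs(X.mean(axis=0)).max() < 1e-12
        assert np.abs(X.std(axis=0, ddof=1) - 1).max() < 1e-12
        assert len(ids) == ds.n_tracks

    def test_nonfinite_tracks_dropped(self, two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        ds.tracks.loc[0, "Tortuosity"] = np.nan
        X, ids = build_feature_matrix(ds, ["Mean Speed", "Tortuosity"])
        assert len(ids) == ds.n_tracks - 1
        assert ds.tracks.loc[0, "unique_track_id"] not in ids

    def test_constant_column_dropped(self, two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        ds.tracks["CONST"] = 1.0
        X, _ = build_feature_matrix(ds, ["Mean Speed", "Directionality", "CONST"])
        assert X.shape[1] == 2

    def test_all_constant_is_error(self, small_scene):
        ds, _ = small_scene
        ds = ds.copy()
        ds.tracks["C1"] = 1.0
        ds.tracks["C2"] = 2.0
        with pytest.raises(ValueError):
            build_feature_matrix(ds, ["C1", "C2"])


class TestEmbedding:
    def test_tsne_shape_and_determinism(self):
        X, _, _ = blob_matrix(40)
        cfg = EmbeddingConfig(method="tsne", seed=42)
        a = embed(X, cfg)
        b = embed(X, cfg)
        assert a.shape == (80, 2)
        assert np.isfinite(a).all()
        assert np.array_equal(a, b)

    def test_too_few_rows_is_error(self):
        X, _, _ = blob_matrix(4)
        with pytest.raises(ValueError, match="n_neighbors"):
            embed(X[:6], EmbeddingConfig(n_neighbors=10))

    def test_umap_separates_distant_blobs(self):
        X, _, truth = blob_matrix(100, sep=10.0)
        coords = embed(X, EmbeddingConfig(seed=42))
        c0, c1 = coords[truth == 0], coords[truth == 1]
        between = np.linalg.norm(c0.mean(axis=0) - c1.mean(axis=0))
        within = max(
            np.quantile(np.linalg.norm(c0 - c0.mean(axis=0), axis=1), 0.95),
            np.quantile(np.linalg.norm(c1 - c1.mean(axis=0), axis=1), 0.95),
        )
        assert between > within


class TestClustering:
    def test_two_blob_recovery(self):
        X, ids, truth = blob_matrix(100)
        labels = cluster_tracks(X, ids, ClusterConfig(
            clustering_data_source="features", min_samples=10, min_cluster_size=50))
        found = labels[labels >= 0]
        assert found.nunique() == 2
        purity = sum(
            pd.Series(truth[labels.to_numpy() == c]).value_counts().iloc[0]
            for c in found.unique()
        ) / len(found)
        assert purity > 0.95

    def test_uniform_noise_mostly_unclustered(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (100, 3))
        ids = pd.Index([f"t::{i}" for i in range(100)])
        labels = cluster_tracks(X, ids, ClusterConfig(
            clustering_data_source="features", min_samples=10, min_cluster_size=90))
        assert (labels == -1).mean() > 0.9

    def test_min_cluster_size_larger_than_n_is_error(self):
        X, ids, _ = blob_matrix(10)
        with pytest.raises(ValueError):
            cluster_tracks(X, ids, ClusterConfig(min_cluster_size=200))


class TestFingerprint:
    @staticmethod
    def scene_with_labels(two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        ids = ds.tracks["unique_track_id"]
        rng = np.random.default_rng(0)
        labels = pd.Series(rng.choice([0, 1, -1], size=len(ids), p=[0.4, 0.4, 0.2]),
                           index=pd.Index(ids))
        return ds, labels

    def test_rows_sum_to_hundred(self, two_condition_scene):
        ds, labels = self.scene_with_labels(two_condition_scene)
        fp = fingerprint(labels, ds)
        assert np.allclose(fp.sum(axis=1), 100.0, atol=1e-9)
        assert "noise" in fp.columns

    def test_half_half_split(self):
        ds = make_dataset([(f"f::{k}", 0, 0.0, 0.0, 0.0) for k in range(4)]
                          + [(f"f::{k}", 1, 1.0, 1.0, 0.0) for k in range(4)])
        labels = pd.Series([0, 0, 1, 1],
                           index=pd.Index([f"f::{k}" for k in range(4)]))
        fp = fingerprint(labels, ds)
        assert fp.loc["A", 0] == 50.0
        assert fp.loc["A", 1] == 50.0

    def test_condition_missing_from_subset_gets_nan(self, two_condition_scene):
        ds, labels = self.scene_with_labels(two_condition_scene)
        slow_ids = ds.tracks.loc[ds.tracks["condition"] == "slow", "unique_track_id"]
        fp = fingerprint(labels[labels.index.isin(slow_ids)], ds)
        assert fp.loc["fast"].isna().all()
        assert np.allclose(fp.loc["slow"].sum(), 100.0)

    def test_designed_enrichment_recovered(self):
        # condition B is enriched 4:1 in cluster 0
        rows, labels = [], {}
        k = 0
        for cond, n0, n1 in (("A", 20, 80), ("B", 80, 20)):
            for i in range(n0 + n1):
                uid = f"{cond}::{k}"
                k += 1
                rows.append((uid, cond, 0 if i < n0 else 1))
        spots = pd.DataFrame([(uid, "f", cond, "R1", 0, 0.0, 0.0, 0.0)
                              for uid, cond, _ in rows],
                             columns=["unique_track_id", "file_name", "condition",
                                      "repeat", "frame", "t", "x", "y"])
        tracks = spots[["unique_track_id", "file_name", "condition", "repeat"]].copy()
        from celltracks.data_model_io import Dataset
        ds = Dataset(spots=spots, tracks=tracks, frame_interval=1.0)
        labels = pd.Series([c for _, _, c in rows],
                           index=pd.Index([u for u, _, _ in rows]))
        fp = fingerprint(labels, ds)
        assert fp.loc["B", 0] / fp.loc["A", 0] == pytest.approx(4.0)


class TestClusterProfile:
    def test_two_cluster_z_scores(self, two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        ids = ds.tracks["unique_track_id"]
        labels = pd.Series([0, 1] * (len(ids) // 2), index=pd.Index(ids))
        ds.tracks["SYNTH"] = np.where(labels.to_numpy() == 0, 1.0, 3.0)
        prof = cluster_profile(ds, labels, ["SYNTH"])
        assert prof.loc[0, "SYNTH"] == pytest.approx(-np.sqrt(0.5))
        assert prof.loc[1, "SYNTH"] == pytest.approx(np.sqrt(0.5))

    def test_equal_means_give_zero_row(self, two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        ids = ds.tracks["unique_track_id"]
        labels = pd.Series([0, 1] * (len(ids) // 2), index=pd.Index(ids))
        ds.tracks["FLAT"] = 7.0
        prof = cluster_profile(ds, labels, ["FLAT"])
        assert (prof["FLAT"] == 0).all()

    def test_single_cluster_is_error(self, two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        ids = ds.tracks["unique_track_id"]
        labels = pd.Series([0] * len(ids), index=pd.Index(ids))
        with pytest.raises(ValueError):
            cluster_profile(ds, labels, ["Mean Speed"])


class TestExemplars:
    def test_centroid_point_ranks_first(self, two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        metrics = ["Mean Speed", "Directionality"]
        X, ids = build_feature_matrix(ds, metrics)
        labels = pd.Series(0, index=ids)
        labels.iloc[: len(ids) // 2] = 1
        ex = exemplar_tracks(ds, labels, metrics, k=3)
        for label, members in labels.groupby(labels):
            z = pd.DataFrame(X, index=ids).loc[members.index]
            centroid = z.mean(axis=0)
            best = (np.linalg.norm(z - centroid, axis=1)).argmin()
            assert ex[int(label)][0] == z.index[best]

    def test_k_larger_than_cluster_returns_all(self, two_condition_scene):
        ds, _ = two_condition_scene
        ds = compute_track_metrics(ds)
        metrics = ["Mean Speed", "Directionality"]
        _, ids = build_feature_matrix(ds, metrics)
        labels = pd.Series(0, index=ids)
        ex = exemplar_tracks(ds, labels, metrics, k=10_000)
        assert len(ex[0]) == len(ids)
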