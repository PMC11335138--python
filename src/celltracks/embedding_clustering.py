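"""Behavioral fingerprinting: feature matrix, 2-D embedding, density
clustering, per-condition fingerprints, cluster profiles and exemplars.

The feature matrix is the z-scored set of selected track metrics (tracks
with any non-finite selected value are dropped, constant columns are
dropped).  Embedding is UMAP (defaults n_neighbors=10, min_dist=0, two
output dimensions) or t-SNE; clustering is HDBSCAN run either on the 2-D
embedding or directly on the feature matrix, with euclidean or canberra
distance.  Noise (label -1) is kept as its own fingerprint category so
per-condition percentages always sum to 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.manifold import TSNE

from .data_model_io import Dataset

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    method: str = "umap"
    n_neighbors: int = 10
    min_dist: float = 0.0
    n_dimension: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.method not in ("umap", "tsne"):
            raise ValueError(f"method must be 'umap' or 'tsne', got {self.method!r}")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")


@dataclass
class ClusterConfig:
    clustering_data_source: str = "embedding"
    min_samples: int = 20
    min_cluster_size: int = 200
    metric: str = "euclidean"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.clustering_data_source not in ("embedding", "features"):
            raise ValueError("clustering_data_source must be 'embedding' or 'features'")
        if self.metric not in ("euclidean", "canberra"):
            raise ValueError(f"metric must be 'euclidean' or 'canberra', got {self.metric!r}")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


def build_feature_matrix(ds: Dataset, metrics: list[str]) -> tuple[np.ndarray, pd.Index]:
    """Z-scored feature matrix (columns: metrics, rows: tracks).

    Tracks with any non-finite selected metric are dropped with a logged
    count; constant columns are dropped with a warning (an all-constant
    selection is an error).  Returns the matrix and the row index of
    ``unique_track_id``.
    """
    if len(metrics) < 2:
        raise ValueError("need >= 2 metric columns for a feature matrix")
    missing = [m for m in metrics if m not in ds.tracks.columns]
    if missing:
        raise KeyError(f"metrics not in track table: {missing}")
    sub = ds.tracks.set_index("unique_track_id")[metrics].astype(float)
    finite = np.isfinite(sub.to_numpy()).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropped %d tracks with non-finite feature values", n_dropped)
    sub = sub.loc[finite]
    sd = sub.std(ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all selected metric columns are constant")
    if constant.any():
        logger.warning("dropping constant metric columns: %s", list(sd.index[constant]))
        sub = sub.loc[:, ~constant]
        sd = sd[~constant]
    z = (sub - sub.mean()) / sd
    return z.to_numpy(float), sub.index


def embed(matrix: np.ndarray, config: EmbeddingConfig | None = None) -> np.ndarray:
    """Project the feature matrix to ``n_dimension`` coordinates.

    Deterministic for a fixed seed (UMAP runs single-threaded when a
    random_state is set); row order is preserved.
    """
    config = config or EmbeddingConfig()
    n = matrix.shape[0]
    if n < config.n_neighbors + 1:
        raise ValueError(f"need >= n_neighbors + 1 = {config.n_neighbors + 1} rows, got {n}")
    if config.method == "umap":
        import umap  # deferred: numba compilation is slow at import

        reducer = umap.UMAP(n_neighbors=config.n_neighbors, min_dist=config.min_dist,
                            n_components=config.n_dimension, random_state=config.seed)
        coords = reducer.fit_transform(matrix)
    else:
        perplexity = min(30.0, max(2.0, (n - 1) / 3))
        reducer = TSNE(n_components=config.n_dimension, perplexity=perplexity,
                       random_state=config.seed, init="pca")
        coords = reducer.fit_transform(matrix)
    return np.asarray(coords, dtype=float)


def cluster_tracks(data: np.ndarray, track_ids: pd.Index,
                   config: ClusterConfig | None = None) -> pd.Series:
    """HDBSCAN labels per track (-1 = noise), indexed by unique_track_id.

    ``data`` is whichever the config's ``clustering_data_source`` selects
    (the 2-D embedding or the z-scored feature matrix).
    """
    config = config or ClusterConfig()
    if config.min_cluster_size > data.shape[0]:
        raise ValueError(
            f"min_cluster_size {config.min_cluster_size} exceeds n = {data.shape[0]}"
        )
    model = HDBSCAN(min_samples=config.min_samples,
                    min_cluster_size=config.min_cluster_size, metric=config.metric,
                    copy=True)
    labels = model.fit_predict(data)
    return pd.Series(labels, index=track_ids, name="cluster")


def fingerprint(assignment: pd.Series, ds: Dataset) -> pd.DataFrame:
    """Per-condition percentage of tracks in each cluster (noise included).

    Rows are conditions, columns cluster labels plus ``noise``; each row
    sums to 100.  Conditions without any clustered track get a NaN row.
    """
    cond = ds.tracks.set_index("unique_track_id")["condition"]
    merged = pd.DataFrame({"cluster": assignment}).join(cond, how="left")
    counts = merged.groupby(["condition", "cluster"]).size().unstack(fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100
    pct.columns = ["noise" if c == -1 else int(c) for c in pct.columns]
    all_conditions = sorted(ds.tracks["condition"].unique())
    absent = set(all_conditions) - set(pct.index)
    if absent:
        logger.warning("conditions absent from clustered subset: %s", sorted(absent))
    return pct.reindex(all_conditions)


def cluster_profile(ds: Dataset, assignment: pd.Series,
                    metrics: list[str]) -> pd.DataFrame:
    """Cluster x metric matrix of z-scores computed across cluster means.

    For each metric, each cell is (cluster mean - grand mean of cluster
    means) / sample SD of cluster means; equal means give a zero column.
    Noise is excluded; fewer than 2 non-noise clusters is an error.
    """
    labels = assignment[assignment >= 0]
    if labels.nunique() < 2:
        raise ValueError("cluster profile needs >= 2 non-noise clusters")
    sub = ds.tracks.set_index("unique_track_id").loc[labels.index, metrics].astype(float)
    sub["cluster"] = labels
    means = sub.groupby("cluster").mean()
    sd = means.std(ddof=1)
    centered = means - means.mean()
    z = centered.div(sd.where(sd > 0, 1.0))  # 0/0 guarded to 0
    z[centered == 0] = z[centered == 0].fillna(0.0)
    return z


def exemplar_tracks(ds: Dataset, assignment: pd.Series, metrics: list[str],
                    k: int = 5) -> dict[int, list[str]]:
    """Per cluster, the k tracks closest to the cluster centroid in z-scored
    feature space; ties broken by track-id order."""
    matrix, ids = build_feature_matrix(ds, metrics)
    z = pd.DataFrame(matrix, index=ids)
    labels = assignment[assignment >= 0]
    if labels.empty:
        raise ValueError("no non-noise clusters")
    out: dict[int, list[str]] = {}
    for label, members in labels.groupby(labels):
        member_ids = [i for i in members.index if i in z.index]
        pts = z.loc[member_ids]
        centroid = pts.mean(axis=0)
        dist = np.linalg.norm(pts.to_numpy() - centroid.to_numpy(), axis=1)
        ranked = sorted(zip(dist, member_ids))
        if k > len(ranked):
            logger.warning("cluster %d has only %d tracks (< k = %d)", label, len(ranked), k)
        out[int(label)] = [tid for _, tid in ranked[:k]]
    return out
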