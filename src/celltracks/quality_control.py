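"""Dataset balance reporting, replicate similarity trees, and balanced
resampling with distribution checks.

Replicate/FOV similarity: each group is summarized by the median of each
selected track metric, features are z-scored across groups, pairwise
distance is 1 - cosine similarity and groups are agglomerated with complete
linkage.  Balanced resampling downsamples every (condition, repeat) cell to
the size of the smallest cell, without replacement and seeded; the
before/after check is a per-condition, per-metric two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp

from .data_model_io import Dataset

logger = logging.getLogger(__name__)


def group_counts(ds: Dataset) -> pd.DataFrame:
    """Track counts per (condition, repeat) cell, plus per-condition totals.

    Every (condition, repeat) directory recorded at compile time appears,
    so an empty repeat folder is reported as 0, not dropped.  The returned
    frame has conditions as rows, repeats as columns and a ``total`` column.
    """
    counts = ds.tracks.groupby(["condition", "repeat"]).size()
    idx = pd.MultiIndex.from_tuples(
        sorted(set(ds.groups) | set(counts.index)), names=["condition", "repeat"]
    )
    counts = counts.reindex(idx, fill_value=0)
    table = counts.unstack("repeat", fill_value=0)
    table["total"] = table.sum(axis=1)
    return table


@dataclass
class SimilarityTree:
    """Complete-linkage agglomeration of group feature vectors."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    distance: str = "cosine_on_zscored_medians"

    def cophenetic_height(self, label_a: str, label_b: str) -> float:
        """Height at which two leaves first share a cluster."""
        from scipy.cluster.hierarchy import cophenet

        dists = cophenet(self.linkage_matrix)
        n = len(self.labels)
        i, j = sorted((self.labels.index(label_a), self.labels.index(label_b)))
        # condensed-matrix offset for pair (i, j)
        k = n * i - i * (i + 1) // 2 + (j - i - 1)
        return float(dists[k])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.linkage_matrix,
                          columns=["child_a", "child_b", "height", "n_leaves"])
        df.attrs["labels"] = self.labels
        return df


def _group_key(ds: Dataset, group_by: str) -> pd.Series:
    if group_by == "fov":
        return ds.tracks["file_name"]
    if group_by == "condition_repeat":
        return ds.tracks["condition"] + "_" + ds.tracks["repeat"]
    raise ValueError(f"group_by must be 'fov' or 'condition_repeat', got {group_by!r}")


def similarity_tree(ds: Dataset, group_by: str = "condition_repeat",
                    metrics: list[str] | None = None) -> SimilarityTree:
    """Hierarchical similarity of FOVs or condition/repeat groups.

    Groups with zero tracks are excluded with a warning; fewer than two
    remaining groups is an error.  Metric columns that are constant across
    groups carry no information for the z-score and are dropped; if every
    column is constant all pairwise distances are defined as 0.
    """
    if metrics is None:
        metrics = [c for c in ds.tracks.columns
                   if pd.api.types.is_numeric_dtype(ds.tracks[c])]
    missing = [m for m in metrics if m not in ds.tracks.columns]
    if missing:
        raise KeyError(f"metrics not in track table: {missing}")
    key = _group_key(ds, group_by)
    medians = ds.tracks[metrics].groupby(key).median()
    empty = medians.isna().all(axis=1)
    if empty.any():
        logger.warning("excluding groups with no usable tracks: %s", list(medians.index[empty]))
        medians = medians[~empty]
    if len(medians) < 2:
        raise ValueError("need >= 2 non-empty groups for a similarity tree")

    sd = medians.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant metric columns before z-scoring", int((~keep).sum()))
    labels = sorted(medians.index.tolist())
    medians = medians.loc[labels]
    if keep.any():
        z = (medians.loc[:, keep] - medians.loc[:, keep].mean()) / sd[keep]
        dist = pdist(z.to_numpy(float), metric="cosine")
        dist = np.clip(dist, 0.0, None)
    else:
        dist = np.zeros(len(labels) * (len(labels) - 1) // 2)
    Z = linkage(dist, method="complete")
    return SimilarityTree(labels=labels, linkage_matrix=Z)


def resample_balanced(ds: Dataset, seed: int | None = None) -> Dataset:
    """Downsample every (condition, repeat) cell to the smallest cell size.

    Sampling is without replacement and seeded; spots of removed tracks are
    removed too.  An empty cell is an error (nothing to sample).
    """
    counts = ds.tracks.groupby(["condition", "repeat"]).size()
    observed = {(c, r) for c, r in counts.index}
    for cell in ds.groups:
        if cell not in observed:
            raise ValueError(f"cannot resample: cell {cell} has no tracks")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for (_, _), grp in ds.tracks.groupby(["condition", "repeat"], sort=True):
        ids = np.sort(grp["unique_track_id"].to_numpy())
        pick = rng.choice(ids, size=m, replace=False)
        kept.extend(pick)
    return ds.select_tracks(kept)


def resampling_check(original: Dataset, resampled: Dataset,
                     metrics: list[str]) -> pd.DataFrame:
    """Per-condition, per-metric KS p-values between original and resampled
    track-metric distributions (identical distributions give p near 1)."""
    for m in metrics:
        if m not in original.tracks.columns or m not in resampled.tracks.columns:
            raise KeyError(f"metric {m!r} missing from one of the datasets")
    conditions = sorted(set(original.tracks["condition"]) & set(resampled.tracks["condition"]))
    table = pd.DataFrame(index=conditions, columns=metrics, dtype=float)
    for cond in conditions:
        orig = original.tracks[original.tracks["condition"] == cond]
        resam = resampled.tracks[resampled.tracks["condition"] == cond]
        for m in metrics:
            a = orig[m].dropna().to_numpy(float)
            b = resam[m].dropna().to_numpy(float)
            table.loc[cond, m] = ks_2samp(a, b).pvalue if len(a) and len(b) else np.nan
    return table
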