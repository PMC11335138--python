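"""PDF plot exports: every figure is drawn from a plain DataFrame so the
``report`` subcommand can regenerate plots from saved CSVs alone."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram


def plot_boxplot_stats(stats: pd.DataFrame, out_path: str | Path) -> None:
    """Tukey boxplots from a tukey_boxplot_stats frame (one box per row)."""
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(stats)), 4))
    for i, row in stats.reset_index(drop=True).iterrows():
        ax.add_patch(plt.Rectangle((i - 0.3, row["q1"]), 0.6, row["q3"] - row["q1"],
                                   fill=False, edgecolor="C0"))
        ax.plot([i - 0.3, i + 0.3], [row["median"]] * 2, color="C1")
        ax.plot([i, i], [row["q3"], row["whisker_high"]], color="C0")
        ax.plot([i, i], [row["whisker_low"], row["q1"]], color="C0")
    labels = stats.apply(
        lambda r: "/".join(str(r[c]) for c in ("condition", "repeat") if c in stats.columns),
        axis=1)
    ax.set_xticks(range(len(stats)), labels, rotation=45, ha="right")
    ax.set_ylabel(stats["metric"].iloc[0] if len(stats) else "")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_mirrored_heatmap(matrix: pd.DataFrame, out_path: str | Path,
                          title: str = "Cohen's d (upper) / p (lower)") -> None:
    fig, ax = plt.subplots(figsize=(1 + 0.8 * len(matrix),) * 2)
    im = ax.imshow(matrix.to_numpy(float), cmap="coolwarm")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(len(matrix.index)):
        for j in range(len(matrix.columns)):
            v = matrix.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.3g}", ha="center", va="center", fontsize=8)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_heatmap(table: pd.DataFrame, out_path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(table.columns), 1 + 0.5 * len(table)))
    im = ax.imshow(table.to_numpy(float), cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(table.index)), table.index, fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_stacked_counts(counts: pd.DataFrame, out_path: str | Path) -> None:
    """Stacked per-repeat track counts per condition."""
    data = counts.drop(columns=["total"], errors="ignore")
    fig, ax = plt.subplots(figsize=(max(4, len(data)), 4))
    bottom = np.zeros(len(data))
    for col in data.columns:
        vals = data[col].to_numpy(float)
        ax.bar(data.index, vals, bottom=bottom, label=str(col))
        for i, (b, v) in enumerate(zip(bottom, vals)):
            if v > 0:
                ax.text(i, b + v / 2, str(int(v)), ha="center", va="center", fontsize=8)
        bottom += vals
    ax.set_ylabel("tracks")
    ax.legend(title="repeat", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_dendrogram(linkage_matrix: np.ndarray, labels: list[str],
                    out_path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(labels)), 4))
    dendrogram(linkage_matrix, labels=labels, ax=ax, leaf_rotation=90)
    ax.set_ylabel("cosine distance (complete linkage)")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_embedding(embedding: pd.DataFrame, out_path: str | Path,
                   color_by: str = "cluster") -> None:
    """Scatter of an embedding frame (dim1, dim2 plus label columns)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, grp in embedding.groupby(color_by):
        ax.scatter(grp["dim1"], grp["dim2"], s=4, label=str(label))
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(markerscale=3, fontsize=7, title=color_by)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_ripley(curve: pd.DataFrame, out_path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["r"], curve["l_minus_r"], color="C0", label="observed")
    if "envelope_low" in curve.columns:
        ax.fill_between(curve["r"], curve["envelope_low"], curve["envelope_high"],
                        color="grey", alpha=0.4, label="CSR envelope")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("r")
    ax.set_ylabel("L(r) - r")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_roi_overlay(spots: pd.DataFrame, roi_vertices: np.ndarray,
                     out_path: str | Path, n_examples: int = 10,
                     distance_column: str = "ROI_DISTANCE") -> None:
    """Validation overlay: sampled spots, their distance circles and the ROI
    boundary, to visually check that distances are measured correctly."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot(roi_vertices[:, 0], roi_vertices[:, 1], color="white", lw=2,
            path_effects=None)
    ax.plot(roi_vertices[:, 0], roi_vertices[:, 1], color="k", lw=1)
    sample = spots.drop_duplicates("unique_track_id").head(n_examples)
    ax.scatter(spots["x"], spots["y"], s=1, color="grey", alpha=0.3)
    for _, row in sample.iterrows():
        ax.scatter([row["x"]], [row["y"]], color="gold", zorder=3)
        circ = plt.Circle((row["x"], row["y"]), row[distance_column],
                          fill=False, color="red", lw=0.8)
        ax.add_patch(circ)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
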