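"""Track-level motility metrics and spot-feature aggregation.

For a track with positions :math:`p_0..p_{n-1}` at times :math:`t_0..t_{n-1}`
(sorted by frame), with steps :math:`v_i = p_{i+1}-p_i`, step lengths
:math:`\\ell_i = |v_i|` and step speeds :math:`s_i = \\ell_i/(t_{i+1}-t_i)`:

* Track Duration = t_{n-1} - t_0
* Total Distance Traveled = sum of step lengths
* TRACK_DISPLACEMENT = |p_{n-1} - p_0|
* Directionality (= CONFINEMENT_RATIO) = displacement / total distance
  (0 when the total distance is 0); Tortuosity is its reciprocal
  (NaN at zero displacement)
* MEAN_STRAIGHT_LINE_SPEED = displacement / duration;
  LINEARITY_OF_FORWARD_PROGRESSION = straight-line speed / mean speed
* MAX_DISTANCE_TRAVELED = max_i |p_i - p_0|
* turning angles are unsigned angles between consecutive steps in [0, pi]
  (0 when a step has zero length); Total Turning Angle is their sum and
  MEAN_DIRECTIONAL_CHANGE_RATE averages angle / leading step duration
* Spatial Coverage = convex-hull area of the positions (0 below 3
  non-collinear points)
* gaps: NUMBER_GAPS counts frame jumps > 1, LONGEST_GAP is the largest
  jump minus 1

Single-spot tracks get zero duration and distances and NaN speed metrics.
The implementation is column-vectorized over the whole spot table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .data_model_io import Dataset

logger = logging.getLogger(__name__)

#: names of all computed metric columns, in output order
METRIC_COLUMNS = [
    "NUMBER_SPOTS", "NUMBER_GAPS", "LONGEST_GAP",
    "Track Duration", "Total Distance Traveled", "TRACK_DISPLACEMENT",
    "Directionality", "CONFINEMENT_RATIO", "Tortuosity",
    "Mean Speed", "Median Speed", "Max Speed", "Min Speed",
    "Speed Standard Deviation", "MEAN_STRAIGHT_LINE_SPEED",
    "LINEARITY_OF_FORWARD_PROGRESSION", "MAX_DISTANCE_TRAVELED",
    "Total Turning Angle", "MEAN_DIRECTIONAL_CHANGE_RATE", "Spatial Coverage",
]

SPOT_AGGREGATE_STATS = ("MEAN", "MEDIAN", "STD", "MIN", "MAX")


def _hull_area(points: np.ndarray) -> float:
    pts = np.unique(points[:, :2], axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0  # collinear


def compute_track_metrics(ds: Dataset) -> Dataset:
    """Append all motility metric columns to the track table.

    Metrics are computed on the current (possibly smoothed) coordinates.
    Returns a new Dataset; the spot table is unchanged.
    """
    spots = ds.spots.sort_values(["unique_track_id", "frame"], kind="mergesort")
    uid = spots["unique_track_id"].to_numpy()
    coords = spots[ds.coordinate_columns].to_numpy(float)
    t = spots["t"].to_numpy(float)
    frame = spots["frame"].to_numpy(int)

    g = spots.groupby("unique_track_id", sort=True)
    n_spots = g.size()
    index = n_spots.index
    first_idx = g.indices  # uid -> positional indices

    # --- step-level quantities (row i describes step i -> i+1) -------------
    same = uid[1:] == uid[:-1]
    steps = np.diff(coords, axis=0)
    dt = np.diff(t)
    dframe = np.diff(frame)
    lengths = np.linalg.norm(steps, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        speeds = lengths / dt
    step_uid = uid[:-1][same]
    sdf = pd.DataFrame({
        "uid": step_uid,
        "length": lengths[same],
        "speed": speeds[same],
        "dt": dt[same],
        "dframe": dframe[same],
    })
    sg = sdf.groupby("uid", sort=True)
    total_dist = sg["length"].sum().reindex(index, fill_value=0.0)
    n_gaps = sg["dframe"].apply(lambda d: int((d > 1).sum())).reindex(index, fill_value=0)
    longest_gap = sg["dframe"].max().reindex(index).fillna(1.0).astype(int) - 1
    longest_gap = longest_gap.clip(lower=0)
    mean_speed = sg["speed"].mean().reindex(index)
    median_speed = sg["speed"].median().reindex(index)
    max_speed = sg["speed"].max().reindex(index)
    min_speed = sg["speed"].min().reindex(index)
    std_speed = sg["speed"].std(ddof=1).reindex(index)

    # --- endpoint quantities ----------------------------------------------
    firsts = g.head(1).set_index("unique_track_id")
    lasts = g.tail(1).set_index("unique_track_id")
    p0 = firsts[ds.coordinate_columns].to_numpy(float)
    p_end = lasts[ds.coordinate_columns].to_numpy(float)
    duration = (lasts["t"] - firsts["t"]).reindex(index)
    displacement = pd.Series(np.linalg.norm(p_end - p0, axis=1), index=firsts.index).reindex(index)

    # distance of every spot from its track's first position
    start_rep = np.concatenate([
        np.repeat(p0[[i]], n_spots.iloc[i], axis=0) for i in range(len(index))
    ]) if len(index) else np.empty((0, coords.shape[1]))
    # spots are grouped contiguously after the sort, in the same sorted order
    order = np.argsort(uid, kind="mergesort")
    dist_from_start = np.linalg.norm(coords[order] - start_rep, axis=1)
    max_dist = (
        pd.Series(dist_from_start, index=uid[order]).groupby(level=0).max().reindex(index)
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        directionality = np.where(total_dist > 0, displacement / total_dist, 0.0)
        tortuosity = np.where(displacement > 0, total_dist / displacement, np.nan)
        msls = np.where(duration > 0, displacement / duration, np.nan)
        linearity = msls / mean_speed

    # --- turning angles (pairs of consecutive steps within a track) -------
    pair = same[1:] & same[:-1]
    v1 = steps[:-1][pair]
    v2 = steps[1:][pair]
    l1 = lengths[:-1][pair]
    l2 = lengths[1:][pair]
    dot = np.einsum("ij,ij->i", v1, v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.clip(dot / (l1 * l2), -1.0, 1.0)
    theta = np.where((l1 > 0) & (l2 > 0), np.arccos(cosang), 0.0)
    pair_uid = uid[:-2][pair]
    pair_dt = dt[1:][pair]  # duration of the leading (second) step
    adf = pd.DataFrame({"uid": pair_uid, "theta": theta, "rate": theta / pair_dt})
    ag = adf.groupby("uid", sort=True)
    total_turn = ag["theta"].sum().reindex(index, fill_value=0.0)
    mean_dcr = ag["rate"].mean().reindex(index)

    # --- convex hull (per-track loop; qhull has no batched interface) -----
    coverage = pd.Series(
        {tid: _hull_area(coords[first_idx[tid]]) for tid in index}, dtype=float
    ).reindex(index)

    metrics = pd.DataFrame({
        "NUMBER_SPOTS": n_spots.astype(int),
        "NUMBER_GAPS": n_gaps.astype(int),
        "LONGEST_GAP": longest_gap.astype(int),
        "Track Duration": duration.astype(float),
        "Total Distance Traveled": total_dist,
        "TRACK_DISPLACEMENT": displacement,
        "Directionality": pd.Series(directionality, index=index),
        "CONFINEMENT_RATIO": pd.Series(directionality, index=index),
        "Tortuosity": pd.Series(tortuosity, index=index),
        "Mean Speed": mean_speed,
        "Median Speed": median_speed,
        "Max Speed": max_speed,
        "Min Speed": min_speed,
        "Speed Standard Deviation": std_speed,
        "MEAN_STRAIGHT_LINE_SPEED": pd.Series(msls, index=index),
        "LINEARITY_OF_FORWARD_PROGRESSION": pd.Series(linearity, index=index),
        "MAX_DISTANCE_TRAVELED": max_dist,
        "Total Turning Angle": total_turn,
        "MEAN_DIRECTIONAL_CHANGE_RATE": mean_dcr,
        "Spatial Coverage": coverage,
    })

    out = ds.copy()
    tracks = out.tracks.drop(columns=[c for c in METRIC_COLUMNS if c in out.tracks.columns])
    out.tracks = tracks.merge(metrics, left_on="unique_track_id", right_index=True, how="left")
    return out


def aggregate_spot_features(ds: Dataset, stats: tuple[str, ...] = SPOT_AGGREGATE_STATS) -> Dataset:
    """Aggregate numeric spot-level feature columns to track level.

    For each spot feature ``F`` and statistic ``S`` a track column ``S_F``
    is added (e.g. ``MEAN_CIRCULARITY``).  NaN spot values are ignored; STD
    is the sample standard deviation and is NaN for single observations.
    """
    bad = set(stats) - set(SPOT_AGGREGATE_STATS)
    if bad:
        raise ValueError(f"unknown aggregation statistics: {sorted(bad)}")
    core = {"unique_track_id", "file_name", "condition", "repeat", "frame", "t",
            "x", "y", "z", "x_raw", "y_raw", "z_raw"}
    feature_cols = [c for c in ds.spots.columns
                    if c not in core and pd.api.types.is_numeric_dtype(ds.spots[c])]
    if not feature_cols:
        logger.warning("no numeric spot feature columns to aggregate")
        return ds.copy()

    agg_funcs = {"MEAN": "mean", "MEDIAN": "median", "STD": lambda s: s.std(ddof=1),
                 "MIN": "min", "MAX": "max"}
    g = ds.spots.groupby("unique_track_id", sort=True)
    pieces = []
    for stat in stats:
        res = g[feature_cols].agg(agg_funcs[stat])
        res.columns = [f"{stat}_{c}" for c in feature_cols]
        pieces.append(res)
    table = pd.concat(pieces, axis=1)

    out = ds.copy()
    drop = [c for c in table.columns if c in out.tracks.columns]
    out.tracks = out.tracks.drop(columns=drop).merge(
        table, left_on="unique_track_id", right_index=True, how="left"
    )
    return out
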