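"""Independent reference implementations used to check the production code.

Everything here is written as plain per-track Python loops over one track's
arrays (stdlib math/statistics, shapely for hull area), deliberately
avoiding the vectorized pandas/scipy path of the package.
"""

from __future__ import annotations

import math
import statistics as pystats

import numpy as np
from shapely.geometry import MultiPoint


def naive_track_metrics(coords: np.ndarray, t: np.ndarray, frames: np.ndarray) -> dict:
    """All motility metrics for one track, via explicit loops.

    ``coords`` is (n, 2) or (n, 3), sorted by frame.
    """
    n = len(coords)
    out: dict[str, float] = {"NUMBER_SPOTS": n}
    if n == 1:
        out.update({
            "NUMBER_GAPS": 0, "LONGEST_GAP": 0, "Track Duration": 0.0,
            "Total Distance Traveled": 0.0, "TRACK_DISPLACEMENT": 0.0,
            "Directionality": 0.0, "CONFINEMENT_RATIO": 0.0,
            "Tortuosity": math.nan, "Mean Speed": math.nan,
            "Median Speed": math.nan, "Max Speed": math.nan,
            "Min Speed": math.nan, "Speed Standard Deviation": math.nan,
            "MEAN_STRAIGHT_LINE_SPEED": math.nan,
            "LINEARITY_OF_FORWARD_PROGRESSION": math.nan,
            "MAX_DISTANCE_TRAVELED": 0.0, "Total Turning Angle": 0.0,
            "MEAN_DIRECTIONAL_CHANGE_RATE": math.nan, "Spatial Coverage": 0.0,
        })
        return out

    steps = []
    lengths = []
    speeds = []
    dts = []
    gaps = []
    for i in range(n - 1):
        v = [coords[i + 1][k] - coords[i][k] for k in range(coords.shape[1])]
        ell = math.sqrt(sum(c * c for c in v))
        dt = t[i + 1] - t[i]
        steps.append(v)
        lengths.append(ell)
        dts.append(dt)
        speeds.append(ell / dt)
        gaps.append(int(frames[i + 1] - frames[i]))

    total = sum(lengths)
    disp = math.sqrt(sum((coords[-1][k] - coords[0][k]) ** 2 for k in range(coords.shape[1])))
    duration = t[-1] - t[0]
    out["NUMBER_GAPS"] = sum(1 for g in gaps if g > 1)
    out["LONGEST_GAP"] = max(gaps) - 1
    out["Track Duration"] = duration
    out["Total Distance Traveled"] = total
    out["TRACK_DISPLACEMENT"] = disp
    out["Directionality"] = disp / total if total > 0 else 0.0
    out["CONFINEMENT_RATIO"] = out["Directionality"]
    out["Tortuosity"] = total / disp if disp > 0 else math.nan
    out["Mean Speed"] = pystats.fmean(speeds)
    out["Median Speed"] = pystats.median(speeds)
    out["Max Speed"] = max(speeds)
    out["Min Speed"] = min(speeds)
    out["Speed Standard Deviation"] = pystats.stdev(speeds) if len(speeds) > 1 else math.nan
    msls = disp / duration if duration > 0 else math.nan
    out["MEAN_STRAIGHT_LINE_SPEED"] = msls
    mean_speed = out["Mean Speed"]
    out["LINEARITY_OF_FORWARD_PROGRESSION"] = (
        msls / mean_speed if mean_speed and not math.isnan(msls) else math.nan
    )
    out["MAX_DISTANCE_TRAVELED"] = max(
        math.sqrt(sum((coords[i][k] - coords[0][k]) ** 2 for k in range(coords.shape[1])))
        for i in range(n)
    )

    thetas = []
    rates = []
    for i in range(len(steps) - 1):
        l1, l2 = lengths[i], lengths[i + 1]
        if l1 > 0 and l2 > 0:
            dot = sum(steps[i][k] * steps[i + 1][k] for k in range(len(steps[i])))
            theta = math.acos(max(-1.0, min(1.0, dot / (l1 * l2))))
        else:
            theta = 0.0
        thetas.append(theta)
        rates.append(theta / dts[i + 1])
    out["Total Turning Angle"] = sum(thetas)
    out["MEAN_DIRECTIONAL_CHANGE_RATE"] = pystats.fmean(rates) if rates else math.nan

    out["Spatial Coverage"] = MultiPoint([tuple(p[:2]) for p in coords]).convex_hull.area
    return out


def naive_metrics_table(ds) -> dict[str, dict]:
    """Oracle metrics for every track of a Dataset, keyed by track id."""
    cols = ["x", "y", "z"] if ds.dimensionality == 3 else ["x", "y"]
    table = {}
    for uid, grp in ds.spots.sort_values(["unique_track_id", "frame"]).groupby("unique_track_id"):
        table[uid] = naive_track_metrics(
            grp[cols].to_numpy(float), grp["t"].to_numpy(float), grp["frame"].to_numpy(int)
        )
    return table


def brute_force_ripley(points: np.ndarray, radii, window) -> np.ndarray:
    """Ripley L(r) - r via an explicit double loop over ordered pairs."""
    xmin, ymin, xmax, ymax = window
    area = (xmax - xmin) * (ymax - ymin)
    n = len(points)
    out = []
    for r in radii:
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(points[i][0] - points[j][0], points[i][1] - points[j][1])
                if d <= r:
                    count += 1
        k = area * count / (n * (n - 1))
        out.append(math.sqrt(k / math.pi) - r)
    return np.array(out)


def random_tracks_dataset(n_tracks: int, seed: int, max_spots: int = 40,
                          gap_prob: float = 0.15, dim: int = 2):
    """Random irregular tracks (variable length, gaps, variable dt) for
    oracle-equivalence checks; includes some degenerate 1-2 spot tracks."""
    import pandas as pd
    from celltracks.data_model_io import Dataset

    rng = np.random.default_rng(seed)
    spot_rows = []
    track_rows = []
    for k in range(n_tracks):
        uid = f"rand::{k}"
        n = int(rng.integers(1, max_spots + 1)) if k % 7 == 0 else int(rng.integers(3, max_spots + 1))
        frames = np.sort(rng.choice(np.arange(3 * n), size=n, replace=False)) \
            if rng.random() < gap_prob else np.arange(n)
        coords = rng.normal(0, 20, size=(n, dim)).cumsum(axis=0)
        if rng.random() < 0.1 and n >= 2:
            coords[1] = coords[0]  # zero-length step
        for i, fr in enumerate(frames):
            row = {"unique_track_id": uid, "file_name": "rand", "condition": "c",
                   "repeat": "r", "frame": int(fr), "t": float(fr) * 2.0,
                   "x": coords[i, 0], "y": coords[i, 1]}
            if dim == 3:
                row["z"] = coords[i, 2]
            spot_rows.append(row)
        track_rows.append({"unique_track_id": uid, "file_name": "rand",
                           "condition": "c", "repeat": "r"})
    spots = pd.DataFrame(spot_rows)
    tracks = pd.DataFrame(track_rows)
    return Dataset(spots=spots, tracks=tracks, frame_interval=2.0, dimensionality=dim)
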