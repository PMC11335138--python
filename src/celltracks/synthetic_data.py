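"""Synthetic tracking datasets with known ground truth.

Tracks are persistent biased random walks in a rectangular field: the step
direction is the unit-normalized persistence-weighted mixture of the
previous direction and a fresh random direction, the step length is drawn
from a normal truncated at zero with mean ``speed_mean * frame_interval``,
and an optional constant bias velocity is added.  Tracks reflect at the
field borders (reflection is flagged in the ground truth).  Frames are
dropped independently with ``frame_drop_prob`` to create gaps.

A scene is a full Condition/Repeat/FOV design; the generator also writes
fixture trees in the supported on-disk dialects (TrackMate model XML,
TrackMate-style CSV with its three auxiliary sub-header rows, and a plain
generic CSV) so the readers can be exercised without real exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree
from scipy.stats import truncnorm

from .data_model_io import TRACK_ID_SEPARATOR, ColumnMap, Dataset
from .spatial_analysis import RoiGeometry

FIXTURE_FORMATS = ("trackmate_xml", "trackmate_csv", "generic_csv")


@dataclass
class MotionModel:
    """Per-condition kinematic parameters of the walk."""

    speed_mean: float = 10.0  # length / time
    speed_sd: float = 3.0
    persistence: float = 0.5  # 0 = uncorrelated steps, 1 = straight line
    bias_vector: tuple[float, float] = (0.0, 0.0)  # drift velocity
    frame_drop_prob: float = 0.0
    n_frames: int = 30
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")
        if not 0 <= self.persistence <= 1:
            raise ValueError(f"persistence must be in [0, 1], got {self.persistence}")
        if not 0 <= self.frame_drop_prob < 1:
            raise ValueError("frame_drop_prob must be in [0, 1)")


@dataclass
class SceneSpec:
    """A full multi-condition experimental design."""

    conditions: dict[str, MotionModel] = field(
        default_factory=lambda: {"control": MotionModel()}
    )
    repeats: int = 3
    fovs_per_repeat: int = 2
    tracks_per_fov: int = 10
    field_size: tuple[float, float] = (500.0, 500.0)
    seed: int = 0
    with_spot_features: bool = False

    def __post_init__(self) -> None:
        if min(self.repeats, self.fovs_per_repeat, self.tracks_per_fov) < 1:
            raise ValueError("all design counts must be >= 1")


def _step_lengths(rng: np.random.Generator, model: MotionModel, n: int) -> np.ndarray:
    mu = model.speed_mean * model.frame_interval
    sd = model.speed_sd * model.frame_interval
    if sd == 0:
        return np.full(n, mu)
    a = (0.0 - mu) / sd
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def _walk(rng: np.random.Generator, model: MotionModel,
          start: np.ndarray, field_size: tuple[float, float]) -> tuple[np.ndarray, bool]:
    """One persistent-biased random walk; returns positions and a flag for
    whether any border reflection occurred."""
    n = model.n_frames
    pos = np.empty((n, 2))
    pos[0] = start
    angle = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.cos(angle), np.sin(angle)])
    lengths = _step_lengths(rng, model, n - 1)
    bias_step = np.asarray(model.bias_vector) * model.frame_interval
    w, h = field_size
    reflected = False
    for i in range(1, n):
        ang = rng.uniform(0, 2 * np.pi)
        fresh = np.array([np.cos(ang), np.sin(ang)])
        mixed = model.persistence * direction + (1 - model.persistence) * fresh
        norm = np.linalg.norm(mixed)
        if norm > 0:
            direction = mixed / norm
        p = pos[i - 1] + direction * lengths[i - 1] + bias_step
        # reflect into the field
        for axis, limit in ((0, w), (1, h)):
            while p[axis] < 0 or p[axis] > limit:
                reflected = True
                if p[axis] < 0:
                    p[axis] = -p[axis]
                else:
                    p[axis] = 2 * limit - p[axis]
        pos[i] = p
    return pos, reflected


def _keep_mask(rng: np.random.Generator, n: int, drop_prob: float) -> np.ndarray:
    if drop_prob == 0:
        return np.ones(n, dtype=bool)
    keep = rng.random(n) >= drop_prob
    if keep.sum() < 2:  # a track needs at least two observed frames
        keep[:] = True
    return keep


def generate_dataset(spec: SceneSpec) -> tuple[Dataset, pd.DataFrame]:
    """Generate a compiled multi-condition Dataset plus its ground truth.

    The ground-truth table has one row per track with the model parameters
    that generated it and bookkeeping (condition, repeat, FOV, spot count,
    reflection flag); it is what the tests compare recovered quantities to.
    """
    rng = np.random.default_rng(spec.seed)
    spot_rows: list[dict] = []
    track_rows: list[dict] = []
    truth_rows: list[dict] = []
    groups: list[tuple[str, str]] = []
    frame_interval = next(iter(spec.conditions.values())).frame_interval

    for cond in sorted(spec.conditions):
        model = spec.conditions[cond]
        for r in range(1, spec.repeats + 1):
            repeat = f"R{r}"
            groups.append((cond, repeat))
            for f in range(1, spec.fovs_per_repeat + 1):
                stem = f"{cond}_{repeat}_FOV{f}"
                for track in range(1, spec.tracks_per_fov + 1):
                    uid = f"{stem}{TRACK_ID_SEPARATOR}{track}"
                    start = rng.uniform([0, 0], spec.field_size)
                    pos, reflected = _walk(rng, model, start, spec.field_size)
                    keep = _keep_mask(rng, model.n_frames, model.frame_drop_prob)
                    frames = np.nonzero(keep)[0]
                    for fr in frames:
                        row = {
                            "unique_track_id": uid, "file_name": stem,
                            "condition": cond, "repeat": repeat,
                            "frame": int(fr), "t": fr * model.frame_interval,
                            "x": pos[fr, 0], "y": pos[fr, 1],
                        }
                        if spec.with_spot_features:
                            row["AREA"] = rng.normal(100.0, 10.0)
                            row["CIRCULARITY"] = float(np.clip(rng.normal(0.7, 0.05), 0, 1))
                        spot_rows.append(row)
                    track_rows.append({"unique_track_id": uid, "file_name": stem,
                                       "condition": cond, "repeat": repeat})
                    truth_rows.append({
                        "unique_track_id": uid, "condition": cond, "repeat": repeat,
                        "file_name": stem, "n_spots": int(keep.sum()),
                        "duration": (frames[-1] - frames[0]) * model.frame_interval,
                        "speed_mean": model.speed_mean, "speed_sd": model.speed_sd,
                        "persistence": model.persistence,
                        "bias_x": model.bias_vector[0], "bias_y": model.bias_vector[1],
                        "reflected": reflected,
                    })

    spots = pd.DataFrame(spot_rows).sort_values(
        ["unique_track_id", "frame"], kind="mergesort").reset_index(drop=True)
    tracks = pd.DataFrame(track_rows).sort_values(
        "unique_track_id", kind="mergesort").reset_index(drop=True)
    ds = Dataset(spots=spots, tracks=tracks, frame_interval=frame_interval,
                 groups=sorted(set(groups)))
    return ds, pd.DataFrame(truth_rows)


def generate_roi_scene(
    spec: SceneSpec,
    edge_x: float = 50.0,
    approach_speed: float = 2.0,
    fraction_approaching: float = 0.5,
) -> tuple[Dataset, RoiGeometry, pd.DataFrame]:
    """Leading-edge scene: a vertical boundary at ``x = edge_x`` plus tracks
    that either drift straight toward the edge at exactly
    ``approach_speed`` (noise-free, so the distance series is analytic) or
    wander per their condition's motion model.

    The ground truth records each track's type, start distance and maximal
    distance to the edge, from which the designed close/far stratum follows.
    """
    if not 0 <= fraction_approaching <= 1:
        raise ValueError(f"fraction_approaching must be in [0, 1], got {fraction_approaching}")
    w, h = spec.field_size
    if not 0 < edge_x < w:
        raise ValueError("edge_x must lie inside the field")
    rng = np.random.default_rng(spec.seed)
    frame_interval = next(iter(spec.conditions.values())).frame_interval

    spot_rows: list[dict] = []
    track_rows: list[dict] = []
    truth_rows: list[dict] = []
    groups: list[tuple[str, str]] = []
    for cond in sorted(spec.conditions):
        model = spec.conditions[cond]
        duration = (model.n_frames - 1) * model.frame_interval
        travel = approach_speed * duration
        if edge_x + travel + 2 >= w:
            raise ValueError("field too narrow for the requested approach travel")
        for r in range(1, spec.repeats + 1):
            repeat = f"R{r}"
            groups.append((cond, repeat))
            for f in range(1, spec.fovs_per_repeat + 1):
                stem = f"{cond}_{repeat}_FOV{f}"
                for track in range(1, spec.tracks_per_fov + 1):
                    uid = f"{stem}{TRACK_ID_SEPARATOR}{track}"
                    approaching = rng.random() < fraction_approaching
                    if approaching:
                        # start far enough that the track never crosses the edge
                        d0 = rng.uniform(travel + 1, w - edge_x - 1)
                        y0 = rng.uniform(0, h)
                        frames = np.arange(model.n_frames)
                        xs = edge_x + d0 - approach_speed * frames * model.frame_interval
                        ys = np.full_like(xs, y0)
                        pos = np.column_stack([xs, ys])
                    else:
                        start = np.array([rng.uniform(edge_x, w), rng.uniform(0, h)])
                        pos, _ = _walk(rng, model, start, spec.field_size)
                    dist = np.abs(pos[:, 0] - edge_x)
                    for fr in range(model.n_frames):
                        spot_rows.append({
                            "unique_track_id": uid, "file_name": stem,
                            "condition": cond, "repeat": repeat,
                            "frame": fr, "t": fr * model.frame_interval,
                            "x": pos[fr, 0], "y": pos[fr, 1],
                        })
                    track_rows.append({"unique_track_id": uid, "file_name": stem,
                                       "condition": cond, "repeat": repeat})
                    truth_rows.append({
                        "unique_track_id": uid, "condition": cond, "repeat": repeat,
                        "approaching": approaching,
                        "start_distance": dist[0], "end_distance": dist[-1],
                        "max_distance": dist.max(),
                        "approach_speed": approach_speed if approaching else 0.0,
                    })

    spots = pd.DataFrame(spot_rows).sort_values(
        ["unique_track_id", "frame"], kind="mergesort").reset_index(drop=True)
    tracks = pd.DataFrame(track_rows).sort_values(
        "unique_track_id", kind="mergesort").reset_index(drop=True)
    ds = Dataset(spots=spots, tracks=tracks, frame_interval=frame_interval,
                 groups=sorted(set(groups)))
    roi = RoiGeometry.from_polygon(np.array([[edge_x, 0.0], [edge_x, h]]))
    return ds, roi, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# fixture writers


def _fmt(v: float) -> str:
    return repr(float(v))


def _write_trackmate_xml(fov_spots: pd.DataFrame, path: Path, frame_interval: float) -> None:
    root = etree.Element("TrackMate", version="7.0.0")
    model = etree.SubElement(root, "Model", spatialunits="um", timeunits="s")
    all_spots = etree.SubElement(model, "AllSpots")
    spot_ids: dict[tuple[str, int], int] = {}
    next_id = 1000
    for frame, grp in fov_spots.groupby("frame", sort=True):
        sif = etree.SubElement(all_spots, "SpotsInFrame", frame=str(int(frame)))
        for _, row in grp.iterrows():
            sid = next_id
            next_id += 1
            spot_ids[(row["unique_track_id"], int(row["frame"]))] = sid
            attrs = {
                "ID": str(sid), "name": f"ID{sid}", "VISIBILITY": "1",
                "FRAME": str(int(row["frame"])), "POSITION_T": _fmt(row["t"]),
                "POSITION_X": _fmt(row["x"]), "POSITION_Y": _fmt(row["y"]),
            }
            for col in fov_spots.columns:
                if col in ("unique_track_id", "file_name", "condition", "repeat",
                           "frame", "t", "x", "y"):
                    continue
                if pd.notna(row[col]):
                    attrs[col] = _fmt(row[col])
            etree.SubElement(sif, "Spot", **attrs)
    all_tracks = etree.SubElement(root.find("Model"), "AllTracks")
    filtered = etree.SubElement(root.find("Model"), "FilteredTracks")
    for uid, grp in fov_spots.groupby("unique_track_id", sort=True):
        source_id = uid.split(TRACK_ID_SEPARATOR, 1)[1]
        frames = sorted(grp["frame"].astype(int))
        track = etree.SubElement(all_tracks, "Track", TRACK_ID=source_id,
                                 name=f"Track_{source_id}",
                                 NUMBER_SPOTS=str(len(frames)))
        for a, b in zip(frames[:-1], frames[1:]):
            etree.SubElement(track, "Edge",
                             SPOT_SOURCE_ID=str(spot_ids[(uid, a)]),
                             SPOT_TARGET_ID=str(spot_ids[(uid, b)]))
        etree.SubElement(filtered, "TrackID", TRACK_ID=source_id)
    settings = etree.SubElement(root, "Settings")
    etree.SubElement(settings, "ImageData", timeinterval=_fmt(frame_interval),
                     spatialunits="um", timeunits="s")
    path.write_bytes(etree.tostring(root, pretty_print=True, xml_declaration=True,
                                    encoding="UTF-8"))


def _write_trackmate_csv(fov_spots: pd.DataFrame, path: Path) -> None:
    feature_cols = [c for c in fov_spots.columns
                    if c not in ("unique_track_id", "file_name", "condition", "repeat",
                                 "frame", "t", "x", "y")]
    header = ["LABEL", "ID", "TRACK_ID", "POSITION_X", "POSITION_Y", "POSITION_T", "FRAME"]
    header += feature_cols
    lines = [",".join(header)]
    # TrackMate writes three auxiliary sub-header rows: long names, units, shortcuts
    lines.append(",".join(["Label", "Spot ID", "Track ID", "X", "Y", "T", "Frame"]
                          + feature_cols))
    lines.append(",".join(["", "", "", "(um)", "(um)", "(s)", ""] + [""] * len(feature_cols)))
    lines.append(",".join(["", "", "", "x", "y", "t", "f"] + [""] * len(feature_cols)))
    sid = 1000
    ordered = fov_spots.sort_values(["unique_track_id", "frame"], kind="mergesort")
    for _, row in ordered.iterrows():
        source_id = row["unique_track_id"].split(TRACK_ID_SEPARATOR, 1)[1]
        vals = [f"ID{sid}", str(sid), source_id, _fmt(row["x"]), _fmt(row["y"]),
                _fmt(row["t"]), str(int(row["frame"]))]
        vals += [_fmt(row[c]) if pd.notna(row[c]) else "" for c in feature_cols]
        lines.append(",".join(vals))
        sid += 1
    path.write_text("\n".join(lines) + "\n")


def _write_generic_csv(fov_spots: pd.DataFrame, path: Path) -> None:
    feature_cols = [c for c in fov_spots.columns
                    if c not in ("unique_track_id", "file_name", "condition", "repeat",
                                 "frame", "t", "x", "y")]
    lines = [",".join(["track_id", "frame", "t", "x", "y"] + feature_cols)]
    ordered = fov_spots.sort_values(["unique_track_id", "frame"], kind="mergesort")
    for _, row in ordered.iterrows():
        source_id = row["unique_track_id"].split(TRACK_ID_SEPARATOR, 1)[1]
        vals = [source_id, str(int(row["frame"])), _fmt(row["t"]),
                _fmt(row["x"]), _fmt(row["y"])]
        vals += [_fmt(row[c]) if pd.notna(row[c]) else "" for c in feature_cols]
        lines.append(",".join(vals))
    path.write_text("\n".join(lines) + "\n")


#: column map for reloading generic_csv fixtures
GENERIC_CSV_MAP = ColumnMap(track_id="track_id", frame="frame", x="x", y="y", t="t")


def write_fixture_tree(ds: Dataset, out_dir: str | Path,
                       formats: tuple[str, ...] = ("generic_csv",)) -> dict[str, Path]:
    """Write the Dataset as Condition/Repeat/FOV trees, one per dialect.

    Returns a mapping format name -> tree root.  Reloading any tree with
    :func:`~celltracks.data_model_io.compile_dataset` reproduces the
    Dataset's coordinates and track memberships.
    """
    if not formats:
        raise ValueError("no fixture formats requested")
    bad = set(formats) - set(FIXTURE_FORMATS)
    if bad:
        raise ValueError(f"unsupported fixture formats: {sorted(bad)}")
    out = Path(out_dir)
    roots: dict[str, Path] = {}
    for fmt in formats:
        roots[fmt] = out / fmt
    for (cond, repeat, stem), fov_spots in ds.spots.groupby(
            ["condition", "repeat", "file_name"], sort=True):
        for fmt in formats:
            fov_dir = roots[fmt] / cond / repeat
            fov_dir.mkdir(parents=True, exist_ok=True)
            if fmt == "trackmate_xml":
                _write_trackmate_xml(fov_spots, fov_dir / f"{stem}.xml", ds.frame_interval)
            elif fmt == "trackmate_csv":
                _write_trackmate_csv(fov_spots, fov_dir / f"{stem}.csv")
            else:
                _write_generic_csv(fov_spots, fov_dir / f"{stem}.csv")
    return roots
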