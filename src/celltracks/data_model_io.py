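"""Unified tracking-data model and readers/writers.

Tracking exports (TrackMate XML, TrackMate-style CSV, generic CSV with a
column map) from a ``root/Condition/Repeat/file`` directory tree are
compiled into a single :class:`Dataset`: a spot table (one row per object
per frame) paired with a track table (one row per track) sharing a globally
unique track key ``"<file stem>::<source track id>"``.

Coordinates are kept in the source's calibrated units; no pixel-to-length
conversion is applied unless the column map declares pixel units together
with a pixel size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .errors import ConfigurationError, FormatError, IntegrityError

logger = logging.getLogger(__name__)

#: canonical spot-table columns, in storage order
CORE_SPOT_COLUMNS = ["unique_track_id", "file_name", "condition", "repeat", "frame", "t", "x", "y"]
TRACK_ID_SEPARATOR = "::"


@dataclass
class ColumnMap:
    """Mapping from source CSV column names to canonical names.

    ``track_id``, ``frame``, ``x`` and ``y`` are required; ``t`` is computed
    as ``frame * frame_interval`` when not mapped.  ``space_unit`` may be
    ``"pixel"`` together with ``pixel_size`` (length per pixel) to convert
    positions to calibrated units on load.
    """

    track_id: str
    frame: str
    x: str
    y: str
    t: str | None = None
    z: str | None = None
    feature_columns: Sequence[str] = ()
    space_unit: str = "um"
    pixel_size: float | None = None

    def validate(self) -> None:
        missing = [name for name in ("track_id", "frame", "x", "y") if not getattr(self, name)]
        if missing:
            raise ConfigurationError(f"column map is missing required mappings: {missing}")
        if self.space_unit == "pixel" and not self.pixel_size:
            raise ConfigurationError("space_unit 'pixel' requires a pixel_size")


#: column map matching TrackMate's spots CSV export
TRACKMATE_CSV_MAP = ColumnMap(
    track_id="TRACK_ID", frame="FRAME", x="POSITION_X", y="POSITION_Y", t="POSITION_T"
)


@dataclass
class Dataset:
    """Paired spot and track tables with calibration metadata.

    ``spots`` has one row per tracked object per frame, ``tracks`` one row
    per track; both carry ``unique_track_id`` and the consistency of the two
    key sets is checked on construction.  ``groups`` records every
    (condition, repeat) directory seen at compile time, including empty ones.
    """

    spots: pd.DataFrame
    tracks: pd.DataFrame
    frame_interval: float
    space_unit: str = "um"
    time_unit: str = "s"
    dimensionality: int = 2
    groups: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise ConfigurationError(f"frame_interval must be > 0, got {self.frame_interval}")
        if self.dimensionality not in (2, 3):
            raise ConfigurationError("dimensionality must be 2 or 3")
        spot_ids = set(self.spots["unique_track_id"])
        track_ids = self.tracks["unique_track_id"]
        if track_ids.duplicated().any():
            dupes = track_ids[track_ids.duplicated()].tolist()[:5]
            raise IntegrityError(f"duplicate unique_track_id in track table: {dupes}")
        if spot_ids != set(track_ids):
            raise IntegrityError("spot and track tables disagree on the set of unique_track_ids")
        if not self.groups:
            self.groups = sorted(
                {(c, r) for c, r in zip(self.spots["condition"], self.spots["repeat"])}
            )

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def coordinate_columns(self) -> list[str]:
        return ["x", "y", "z"] if self.dimensionality == 3 else ["x", "y"]

    def copy(self) -> "Dataset":
        return Dataset(
            spots=self.spots.copy(),
            tracks=self.tracks.copy(),
            frame_interval=self.frame_interval,
            space_unit=self.space_unit,
            time_unit=self.time_unit,
            dimensionality=self.dimensionality,
            groups=list(self.groups),
        )

    def select_tracks(self, track_ids: Iterable[str]) -> "Dataset":
        """Return a new Dataset restricted to the given tracks."""
        keep = set(track_ids)
        return Dataset(
            spots=self.spots[self.spots["unique_track_id"].isin(keep)].reset_index(drop=True),
            tracks=self.tracks[self.tracks["unique_track_id"].isin(keep)].reset_index(drop=True),
            frame_interval=self.frame_interval,
            space_unit=self.space_unit,
            time_unit=self.time_unit,
            dimensionality=self.dimensionality,
            groups=list(self.groups),
        )


def _sort_tables(spots: pd.DataFrame, tracks: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    spots = spots.sort_values(["unique_track_id", "frame"], kind="mergesort").reset_index(drop=True)
    tracks = tracks.sort_values("unique_track_id", kind="mergesort").reset_index(drop=True)
    return spots, tracks


def load_trackmate_xml(
    path: str | Path,
    frame_interval: float | None = None,
    *,
    condition: str = "",
    repeat: str = "",
) -> Dataset:
    """Load a single-FOV TrackMate model XML file.

    Spots are read from ``AllSpots``, track membership from the edges in
    ``AllTracks``; spots not referenced by any track are dropped (their
    count is logged).  Numeric track-level features other than the track id
    (e.g. ``NUMBER_SPLITS``) are carried into the track table as imported
    columns.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed TrackMate XML in {path.name}: {exc}") from exc
    root = tree.getroot()
    model = root if root.tag == "Model" else root.find(".//Model")
    if model is None:
        raise FormatError(f"{path.name}: no <Model> element found")
    all_spots = model.find("AllSpots")
    all_tracks = model.find("AllTracks")
    if all_spots is None or all_tracks is None:
        raise FormatError(f"{path.name}: missing <AllSpots> or <AllTracks> section")

    if frame_interval is None:
        settings = root.find(".//ImageData")
        frame_interval = float(settings.get("timeinterval", 1.0)) if settings is not None else 1.0

    spot_rows: dict[int, dict] = {}
    for spot in all_spots.iter("Spot"):
        sid = int(spot.get("ID"))
        row = {
            "frame": int(float(spot.get("FRAME"))),
            "t": float(spot.get("POSITION_T", "nan")),
            "x": float(spot.get("POSITION_X")),
            "y": float(spot.get("POSITION_Y")),
        }
        if spot.get("POSITION_Z") is not None:
            row["z"] = float(spot.get("POSITION_Z"))
        for key, value in spot.attrib.items():
            if key in ("ID", "name", "FRAME", "POSITION_X", "POSITION_Y", "POSITION_Z", "POSITION_T", "VISIBILITY"):
                continue
            try:
                row[key] = float(value)
            except ValueError:
                continue
        spot_rows[sid] = row

    file_stem = path.stem
    records: list[dict] = []
    track_records: list[dict] = []
    assigned: set[int] = set()
    for track in all_tracks.iter("Track"):
        source_id = track.get("TRACK_ID")
        uid = f"{file_stem}{TRACK_ID_SEPARATOR}{source_id}"
        members: set[int] = set()
        for edge in track.iter("Edge"):
            for attr in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID"):
                sid = int(float(edge.get(attr)))
                if sid not in spot_rows:
                    raise IntegrityError(
                        f"{path.name}: edge of track {source_id} references missing spot {sid}"
                    )
                members.add(sid)
        trow: dict = {"unique_track_id": uid, "file_name": file_stem,
                      "condition": condition, "repeat": repeat}
        for key, value in track.attrib.items():
            if key in ("TRACK_ID", "name"):
                continue
            try:
                trow[key] = float(value)
            except ValueError:
                continue
        track_records.append(trow)
        assigned |= members
        for sid in members:
            rec = dict(spot_rows[sid])
            rec.update(unique_track_id=uid, file_name=file_stem,
                       condition=condition, repeat=repeat)
            records.append(rec)

    n_untracked = len(spot_rows) - len(assigned)
    if n_untracked:
        logger.info("%s: dropped %d spots not assigned to any track", path.name, n_untracked)
    if not records:
        raise FormatError(f"{path.name}: no tracked spots found")

    spots = pd.DataFrame.from_records(records)
    if spots["t"].isna().all():
        spots["t"] = spots["frame"] * frame_interval
    tracks = pd.DataFrame.from_records(track_records)
    spots, tracks = _sort_tables(spots, tracks)
    dim = 3 if "z" in spots.columns and spots["z"].notna().any() else 2
    return Dataset(spots=spots, tracks=tracks, frame_interval=frame_interval, dimensionality=dim)


def load_tracking_csv(
    spots_path: str | Path,
    column_map: ColumnMap,
    frame_interval: float = 1.0,
    *,
    trackmate_dialect: bool = False,
    condition: str = "",
    repeat: str = "",
) -> Dataset:
    """Load a single-FOV spot CSV through a :class:`ColumnMap`.

    ``trackmate_dialect=True`` skips the three auxiliary sub-header rows
    (long names / units / abbreviations) that TrackMate writes below the
    header.  Rows with non-finite positions are rejected with a logged count.
    """
    column_map.validate()
    path = Path(spots_path)
    skiprows = [1, 2, 3] if trackmate_dialect else None
    raw = pd.read_csv(path, skiprows=skiprows, float_precision="round_trip")
    required = {"track_id": column_map.track_id, "frame": column_map.frame,
                "x": column_map.x, "y": column_map.y}
    missing = [src for src in required.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path.name}: mapped columns not in CSV: {missing}")

    file_stem = path.stem
    out = pd.DataFrame()
    source_ids = raw[column_map.track_id]
    tracked = source_ids.notna()
    n_untracked = int((~tracked).sum())
    if n_untracked:
        logger.info("%s: dropped %d untracked spots", path.name, n_untracked)
    raw = raw[tracked]
    source_ids = source_ids[tracked]
    # integer-looking ids rendered without a trailing ".0"
    ids = source_ids.map(lambda v: str(int(v)) if isinstance(v, float) and float(v).is_integer() else str(v))
    out["unique_track_id"] = file_stem + TRACK_ID_SEPARATOR + ids
    out["file_name"] = file_stem
    out["condition"] = condition
    out["repeat"] = repeat
    out["frame"] = pd.to_numeric(raw[column_map.frame]).astype(int)
    scale = column_map.pixel_size if column_map.space_unit == "pixel" else 1.0
    out["x"] = pd.to_numeric(raw[column_map.x], errors="coerce") * scale
    out["y"] = pd.to_numeric(raw[column_map.y], errors="coerce") * scale
    if column_map.t is not None and column_map.t in raw.columns:
        out["t"] = pd.to_numeric(raw[column_map.t], errors="coerce")
    else:
        out["t"] = out["frame"] * frame_interval
    if column_map.z is not None and column_map.z in raw.columns:
        out["z"] = pd.to_numeric(raw[column_map.z], errors="coerce") * scale
    for col in column_map.feature_columns:
        if col in raw.columns:
            out[col] = pd.to_numeric(raw[col], errors="coerce")

    finite = np.isfinite(out["x"]) & np.isfinite(out["y"])
    if (~finite).any():
        logger.warning("%s: rejected %d rows with non-finite positions", path.name, int((~finite).sum()))
        out = out[finite]
    if out.empty:
        raise FormatError(f"{path.name}: no valid spot rows")

    tracks = pd.DataFrame({"unique_track_id": out["unique_track_id"].unique()})
    tracks["file_name"] = file_stem
    tracks["condition"] = condition
    tracks["repeat"] = repeat
    spots, tracks = _sort_tables(out, tracks)
    dim = 3 if "z" in spots.columns and spots["z"].notna().any() else 2
    return Dataset(spots=spots, tracks=tracks, frame_interval=frame_interval, dimensionality=dim)


def _merge_fragments(fragments: list[Dataset], groups: list[tuple[str, str]]) -> Dataset:
    spots = pd.concat([f.spots for f in fragments], ignore_index=True)
    tracks = pd.concat([f.tracks for f in fragments], ignore_index=True)
    if tracks["unique_track_id"].duplicated().any():
        dupes = tracks.loc[tracks["unique_track_id"].duplicated(), "unique_track_id"].tolist()[:5]
        raise IntegrityError(f"duplicate unique_track_id after compilation: {dupes}")
    spots, tracks = _sort_tables(spots, tracks)
    first = fragments[0]
    dim = max(f.dimensionality for f in fragments)
    return Dataset(spots=spots, tracks=tracks, frame_interval=first.frame_interval,
                   space_unit=first.space_unit, time_unit=first.time_unit,
                   dimensionality=dim, groups=sorted(set(groups)))


def compile_dataset(
    root_dir: str | Path,
    format: str = "trackmate_xml",
    column_map: ColumnMap | None = None,
    frame_interval: float = 1.0,
    *,
    trackmate_dialect: bool = False,
) -> Dataset:
    """Compile a ``root/Condition/Repeat/files`` tree into one Dataset.

    The first-level directory name becomes ``condition``, the second-level
    name ``repeat``; ``unique_track_id`` is the file stem joined to the
    source track id, which is collision-proof across fields of view.
    """
    root = Path(root_dir)
    if format not in ("trackmate_xml", "csv"):
        raise ConfigurationError(f"unknown format {format!r}")
    if format == "csv" and column_map is None:
        column_map = TRACKMATE_CSV_MAP
    suffix = ".xml" if format == "trackmate_xml" else ".csv"

    fragments: list[Dataset] = []
    groups: list[tuple[str, str]] = []
    for cond_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for rep_dir in sorted(p for p in cond_dir.iterdir() if p.is_dir()):
            groups.append((cond_dir.name, rep_dir.name))
            for f in sorted(rep_dir.glob(f"*{suffix}")):
                if format == "trackmate_xml":
                    frag = load_trackmate_xml(f, frame_interval,
                                              condition=cond_dir.name, repeat=rep_dir.name)
                else:
                    frag = load_tracking_csv(f, column_map, frame_interval,
                                             trackmate_dialect=trackmate_dialect,
                                             condition=cond_dir.name, repeat=rep_dir.name)
                fragments.append(frag)
    if not fragments:
        raise ConfigurationError(f"no {suffix} files found under {root}")
    return _merge_fragments(fragments, groups)


def save_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Write ``spots.csv``, ``tracks.csv`` and a ``dataset.json`` sidecar.

    Floats are written at full ``repr`` precision so that
    ``load_saved(save_dataset(ds))`` round-trips exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.spots.to_csv(out / "spots.csv", index=False)
    ds.tracks.to_csv(out / "tracks.csv", index=False)
    meta = {
        "frame_interval": ds.frame_interval,
        "space_unit": ds.space_unit,
        "time_unit": ds.time_unit,
        "dimensionality": ds.dimensionality,
        "groups": [list(g) for g in ds.groups],
        "n_tracks": ds.n_tracks,
        "n_spots": ds.n_spots,
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def load_saved(out_dir: str | Path) -> Dataset:
    """Load a Dataset previously written by :func:`save_dataset`."""
    out = Path(out_dir)
    for name in ("spots.csv", "tracks.csv", "dataset.json"):
        if not (out / name).exists():
            raise FormatError(f"{out}: missing {name}")
    meta = json.loads((out / "dataset.json").read_text())
    str_cols = ["unique_track_id", "file_name", "condition", "repeat"]
    spots = pd.read_csv(out / "spots.csv", dtype={c: str for c in str_cols},
                        float_precision="round_trip")
    tracks = pd.read_csv(out / "tracks.csv", dtype={c: str for c in str_cols},
                         float_precision="round_trip")
    return Dataset(spots=spots, tracks=tracks,
                   frame_interval=meta["frame_interval"],
                   space_unit=meta["space_unit"], time_unit=meta["time_unit"],
                   dimensionality=meta["dimensionality"],
                   groups=[tuple(g) for g in meta["groups"]])
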