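"""Track smoothing and filtering applied before metric computation.

Smoothing replaces each coordinate by a centered moving average over up to
``window`` spots (windows truncate at track ends — no positions are
invented).  Filtering removes whole tracks that fail duration, spot-count or
path-length thresholds; duration is inclusive (kept when equal), spot count
and total distance are strict, matching "more than N spots" / "greater than
D" phrasing.  A spot threshold of at most 1 or a zero duration/distance
threshold disables that rule, so the all-default spec is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import Dataset
from .errors import ConfigurationError

__all__ = ["FilterSpec", "smooth_tracks", "filter_tracks"]


@dataclass
class FilterSpec:
    """Keep-if thresholds: duration >= min_duration, n_spots > min_spots,
    total distance > min_total_distance."""

    min_duration: float = 0.0
    min_spots: int = 1
    min_total_distance: float = 0.0

    def __post_init__(self) -> None:
        for name in ("min_duration", "min_spots", "min_total_distance"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and non-negative, got {v}")


def smooth_tracks(ds: Dataset, window: int) -> Dataset:
    """Centered moving-average smoothing of per-track coordinates.

    ``window`` must be odd.  Original coordinates are preserved in
    ``<coord>_raw`` companion columns (only written the first time, so
    re-smoothing keeps the true originals); frames and times are unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"smoothing window must be an odd integer >= 1, got {window}")
    out = ds.copy()
    spots = out.spots
    for col in ds.coordinate_columns:
        raw_col = f"{col}_raw"
        if raw_col not in spots.columns:
            spots[raw_col] = spots[col]
        smoothed = (
            spots.groupby("unique_track_id", sort=False)[raw_col]
            .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
        )
        spots[col] = smoothed
    return out


def filter_tracks(ds: Dataset, spec: FilterSpec) -> tuple[Dataset, pd.DataFrame]:
    """Remove tracks failing any FilterSpec criterion from both tables.

    Returns the filtered Dataset and a one-row-per-criterion report with the
    number of tracks removed by each rule (a track failing several rules is
    counted under each).
    """
    spots = ds.spots
    g = spots.groupby("unique_track_id", sort=False)
    n_spots = g.size()
    duration = g["t"].max() - g["t"].min()

    coords = spots[ds.coordinate_columns].to_numpy(float)
    diffs = np.diff(coords, axis=0)
    step_len = np.linalg.norm(diffs, axis=1)
    same_track = spots["unique_track_id"].to_numpy()[1:] == spots["unique_track_id"].to_numpy()[:-1]
    step_df = pd.DataFrame({
        "unique_track_id": spots["unique_track_id"].to_numpy()[1:][same_track],
        "step": step_len[same_track],
    })
    total_dist = step_df.groupby("unique_track_id")["step"].sum()
    total_dist = total_dist.reindex(n_spots.index, fill_value=0.0)

    keep = pd.Series(True, index=n_spots.index)
    report_rows = []
    if spec.min_duration > 0:
        ok = duration >= spec.min_duration
        report_rows.append(("min_duration", spec.min_duration, int((~ok).sum())))
        keep &= ok
    if spec.min_spots > 1:
        ok = n_spots > spec.min_spots
        report_rows.append(("min_spots", spec.min_spots, int((~ok).sum())))
        keep &= ok
    if spec.min_total_distance > 0:
        ok = total_dist > spec.min_total_distance
        report_rows.append(("min_total_distance", spec.min_total_distance, int((~ok).sum())))
        keep &= ok

    report = pd.DataFrame(report_rows, columns=["criterion", "threshold", "n_removed"])
    kept_ids = keep.index[keep]
    return ds.select_tracks(kept_ids), report
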