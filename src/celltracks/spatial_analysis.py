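"""Spatial point-pattern analysis and region-of-interest proximity metrics.

Ripley's K is estimated without analytic edge correction as
``K(r) = |A| / (n (n-1)) * sum_{i != j} 1[d_ij <= r]`` inside a rectangular
observation window; the variance-stabilized ``L(r) - r = sqrt(K/pi) - r``
is reported, with a Monte-Carlo envelope from seeded uniform (CSR)
simulations of the same n in the same window, so the edge bias is shared
between observation and null.

ROI proximity: every spot gets its unsigned Euclidean distance to the ROI
boundary (polygon: exact point-to-segment distance via shapely; mask:
Euclidean distance transform of the boundary pixels times the pixel size),
and per-track summary metrics with an ``_edge`` suffix are derived from the
per-track distance series, including DirectionMovement =
EndDistance - StartDistance (positive: the object ended farther from the
edge than it started) and TrendSlope, the least-squares slope of distance
against time.  Only 2-D + time data are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import binary_erosion, distance_transform_edt
from scipy.spatial.distance import pdist
from shapely.geometry import LineString, Polygon

from .data_model_io import Dataset
from .errors import DimensionalityError

logger = logging.getLogger(__name__)

SPOT_DISTANCE_COLUMN = "ROI_DISTANCE"
EDGE_METRIC_COLUMNS = [
    "MaxDistance_edge", "MinDistance_edge", "StartDistance_edge",
    "EndDistance_edge", "MedianDistance_edge", "StdDevDistance_edge",
    "DirectionMovement_edge", "AvgRateChange_edge", "PercentageChange_edge",
    "TrendSlope_edge",
]


@dataclass
class RipleyResult:
    radii: np.ndarray
    l_minus_r: np.ndarray
    envelope_low: np.ndarray | None
    envelope_high: np.ndarray | None
    n_points: int
    window: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)
    n_simulations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"r": self.radii, "l_minus_r": self.l_minus_r})
        if self.envelope_low is not None:
            df["envelope_low"] = self.envelope_low
            df["envelope_high"] = self.envelope_high
        return df


class RoiGeometry:
    """Region-of-interest boundary in calibrated coordinates.

    Built either from a vertex list (closed polygon if the loop is closed,
    otherwise an open boundary polyline — e.g. a monolayer leading edge) or
    from a binary mask plus a pixel size.
    """

    def __init__(self, boundary: shapely.Geometry | None = None,
                 mask: np.ndarray | None = None, pixel_size: float = 1.0):
        if boundary is None and mask is None:
            raise ValueError("ROI needs either a boundary geometry or a mask")
        self.boundary = boundary
        self.mask = mask
        self.pixel_size = pixel_size
        self._edt: np.ndarray | None = None
        if mask is not None:
            mask = np.asarray(mask).astype(bool)
            if not mask.any():
                raise ValueError("ROI mask is empty")
            # border_value=1: where the ROI touches the image border there is
            # no observable boundary, so the rim must not count as edge
            interior = binary_erosion(mask, border_value=1)
            edge = mask & ~interior
            self.mask = mask
            # distance (in pixels) from each pixel center to the nearest boundary pixel
            self._edt = distance_transform_edt(~edge)

    @classmethod
    def from_polygon(cls, vertices: np.ndarray) -> "RoiGeometry":
        vertices = np.asarray(vertices, dtype=float)
        if len(vertices) < 2:
            raise ValueError("polygon ROI needs >= 2 vertices")
        closed = len(vertices) >= 4 and np.allclose(vertices[0], vertices[-1])
        if closed:
            poly = Polygon(vertices)
            if not poly.is_valid:
                raise ValueError("ROI polygon is self-intersecting or otherwise invalid")
            geom = poly.exterior
        else:
            geom = LineString(vertices)
        return cls(boundary=geom)

    @classmethod
    def from_vertex_csv(cls, path) -> "RoiGeometry":
        df = pd.read_csv(path)
        return cls.from_polygon(df[["x", "y"]].to_numpy(float))

    @classmethod
    def from_mask_tiff(cls, path, pixel_size: float) -> "RoiGeometry":
        import tifffile

        mask = tifffile.imread(path) > 0
        return cls(mask=mask, pixel_size=pixel_size)

    def distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Unsigned distance from points to the ROI boundary."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.boundary is not None:
            pts = shapely.points(x, y)
            return shapely.distance(pts, self.boundary)
        # mask route: nearest-pixel lookup in the boundary distance transform
        rows = np.clip(np.rint(y / self.pixel_size).astype(int), 0, self._edt.shape[0] - 1)
        cols = np.clip(np.rint(x / self.pixel_size).astype(int), 0, self._edt.shape[1] - 1)
        return self._edt[rows, cols] * self.pixel_size


def ripley_l(points: np.ndarray, radii: np.ndarray,
             window: tuple[float, float, float, float]) -> np.ndarray:
    """L(r) - r for a 2-D point set in a rectangular window."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise DimensionalityError("Ripley analysis supports 2-D point sets only")
    n = len(points)
    if n < 2:
        raise ValueError("Ripley's L needs >= 2 points")
    xmin, ymin, xmax, ymax = window
    area = (xmax - xmin) * (ymax - ymin)
    if area <= 0:
        raise ValueError("window has non-positive area")
    radii = np.asarray(radii, dtype=float)
    d = pdist(points)
    # each unordered pair counts twice in the i != j sum
    counts = 2.0 * np.searchsorted(np.sort(d), radii, side="right")
    k = area * counts / (n * (n - 1))
    return np.sqrt(k / np.pi) - radii


def csr_envelope(n_points: int, window: tuple[float, float, float, float],
                 radii: np.ndarray, n_simulations: int = 100,
                 alpha: float = 0.05, seed: int | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise alpha/2 and 1 - alpha/2 quantiles of L(r) - r under CSR."""
    if n_points < 2:
        raise ValueError("CSR envelope needs >= 2 points")
    if n_simulations < 20:
        logger.warning("n_simulations = %d < 20: envelope quantiles are unstable", n_simulations)
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = window
    radii = np.asarray(radii, dtype=float)
    sims = np.empty((n_simulations, len(radii)))
    for i in range(n_simulations):
        pts = np.column_stack([rng.uniform(xmin, xmax, n_points),
                               rng.uniform(ymin, ymax, n_points)])
        sims[i] = ripley_l(pts, radii, window)
    low = np.quantile(sims, alpha / 2, axis=0)
    high = np.quantile(sims, 1 - alpha / 2, axis=0)
    return low, high


def ripley_analysis(ds: Dataset, radii: np.ndarray,
                    window: tuple[float, float, float, float] | None = None,
                    point_rule: str = "first", n_simulations: int = 100,
                    alpha: float = 0.05, seed: int | None = None) -> RipleyResult:
    """Ripley's L - r with CSR envelope on one point per track.

    ``point_rule`` selects the representative point: the track's position at
    its first frame (default, avoids temporal pseudo-replication), its mean
    position, or ``frame:<k>``.
    """
    if ds.dimensionality != 2:
        raise DimensionalityError("spatial analysis supports 2-D + time datasets only")
    g = ds.spots.sort_values(["unique_track_id", "frame"]).groupby("unique_track_id")
    if point_rule == "first":
        pts = g[["x", "y"]].first().to_numpy(float)
    elif point_rule == "mean":
        pts = g[["x", "y"]].mean().to_numpy(float)
    elif point_rule.startswith("frame:"):
        k = int(point_rule.split(":", 1)[1])
        sel = ds.spots[ds.spots["frame"] == k]
        pts = sel.groupby("unique_track_id")[["x", "y"]].first().to_numpy(float)
    else:
        raise ValueError(f"unknown point_rule {point_rule!r}")
    if window is None:
        window = (float(pts[:, 0].min()), float(pts[:, 1].min()),
                  float(pts[:, 0].max()), float(pts[:, 1].max()))
    radii = np.asarray(radii, dtype=float)
    curve = ripley_l(pts, radii, window)
    low, high = csr_envelope(len(pts), window, radii, n_simulations, alpha, seed)
    return RipleyResult(radii=radii, l_minus_r=curve, envelope_low=low,
                        envelope_high=high, n_points=len(pts), window=window,
                        n_simulations=n_simulations, seed=seed)


def distance_to_roi(ds: Dataset, roi: RoiGeometry) -> Dataset:
    """Append the per-spot unsigned distance to the ROI boundary."""
    if ds.dimensionality != 2:
        raise DimensionalityError("ROI proximity supports 2-D + time datasets only")
    out = ds.copy()
    out.spots[SPOT_DISTANCE_COLUMN] = roi.distance(
        out.spots["x"].to_numpy(float), out.spots["y"].to_numpy(float)
    )
    return out


def roi_track_metrics(ds: Dataset) -> Dataset:
    """Per-track summaries of the spot distance-to-edge series.

    Single-spot tracks get NaN rate/slope; PercentageChange is NaN when the
    start distance is zero.
    """
    if SPOT_DISTANCE_COLUMN not in ds.spots.columns:
        raise KeyError(f"run distance_to_roi first: no {SPOT_DISTANCE_COLUMN} spot column")
    rows = {}
    for uid, grp in ds.spots.sort_values(["unique_track_id", "frame"]).groupby("unique_track_id"):
        d = grp[SPOT_DISTANCE_COLUMN].to_numpy(float)
        t = grp["t"].to_numpy(float)
        start, end = d[0], d[-1]
        duration = t[-1] - t[0]
        move = end - start
        if len(d) >= 2:
            slope = float(np.polyfit(t, d, 1)[0])
            rate = move / duration if duration > 0 else np.nan
            std = float(np.std(d, ddof=1))
        else:
            slope = rate = std = np.nan
        rows[uid] = {
            "MaxDistance_edge": d.max(),
            "MinDistance_edge": d.min(),
            "StartDistance_edge": start,
            "EndDistance_edge": end,
            "MedianDistance_edge": float(np.median(d)),
            "StdDevDistance_edge": std,
            "DirectionMovement_edge": move,
            "AvgRateChange_edge": rate,
            "PercentageChange_edge": 100.0 * move / start if start != 0 else np.nan,
            "TrendSlope_edge": slope,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    out = ds.copy()
    drop = [c for c in EDGE_METRIC_COLUMNS if c in out.tracks.columns]
    out.tracks = out.tracks.drop(columns=drop).merge(
        table, left_on="unique_track_id", right_index=True, how="left"
    )
    return out


def stratify_by_distance(ds: Dataset, threshold: float = 75.0) -> Dataset:
    """Label tracks close/far by their maximal distance to the edge.

    ``close`` when MaxDistance_edge <= threshold (ties go to close), else
    ``far``; the label lands in the ``EDGE_STRATUM`` track column so the
    statistics module can compare conditions within a stratum.
    """
    if "MaxDistance_edge" not in ds.tracks.columns:
        raise KeyError("run roi_track_metrics first: no MaxDistance_edge column")
    out = ds.copy()
    out.tracks["EDGE_STRATUM"] = np.where(
        out.tracks["MaxDistance_edge"] <= threshold, "close", "far"
    )
    return out
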