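import math

import numpy as np
import pandas as pd
import pytest

from celltracks import (
    MotionModel,
    RoiGeometry,
    SceneSpec,
    csr_envelope,
    distance_to_roi,
    generate_roi_scene,
    ripley_analysis,
    ripley_l,
    roi_track_metrics,
    stratify_by_distance,
)
from celltracks.errors import DimensionalityError
from celltracks.spatial_analysis import SPOT_DISTANCE_COLUMN
from conftest import make_dataset
from oracles import brute_force_ripley

UNIT_SQUARE = (0.0, 0.0, 1.0, 1.0)


def thomas_process(rng, parent_rate=5, offspring=20, sigma=0.02):
    """Clustered (Thomas) point process in the unit square."""
    n_parents = max(1, rng.poisson(parent_rate))
    parents = rng.uniform(0, 1, (n_parents, 2))
    pts = parents[rng.integers(0, n_parents, n_parents * offspring)]
    pts = pts + rng.normal(0, sigma, pts.shape)
    return np.clip(pts, 0, 1)


class TestRipley:
    def test_two_point_closed_form(self):
        # K = area * 2 / (2*1) = 1 at r >= pairwise distance
        pts = np.array([[0.25, 0.5], [0.25 + 0.5, 0.5]])
        out = ripley_l(pts, np.array([0.5]), UNIT_SQUARE)
        assert out[0] == pytest.approx(math.sqrt(1 / math.pi) - 0.5)

    def test_below_min_distance_gives_minus_r(self):
        pts = np.array([[0.1, 0.1], [0.9, 0.9]])
        r = np.array([0.05, 0.2])
        assert np.allclose(ripley_l(pts, r, UNIT_SQUARE), -r)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (120, 2))
        r = np.linspace(0.01, 0.4, 12)
        assert np.allclose(ripley_l(pts, r, UNIT_SQUARE),
                           brute_force_ripley(pts, r, UNIT_SQUARE), atol=1e-12)

    def test_csr_mean_near_zero_at_small_radii(self):
        rng = np.random.default_rng(1)
        r = np.linspace(0.02, 0.1, 5)
        curves = [ripley_l(rng.uniform(0, 1, (100, 2)), r, UNIT_SQUARE)
                  for _ in range(100)]
        assert np.abs(np.mean(curves, axis=0)).max() < 0.015

    def test_envelope_contains_zero_and_is_ordered(self):
        r = np.linspace(0.02, 0.1, 5)
        lo, hi = csr_envelope(100, UNIT_SQUARE, r, n_simulations=100, seed=2)
        assert (lo <= hi).all()
        assert (lo < 0).all() and (hi > 0).all()

    def test_thomas_process_exceeds_envelope(self):
        r = np.linspace(0.02, 0.1, 9)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            pts = thomas_process(rng)
            curve = ripley_l(pts, r, UNIT_SQUARE)
            _, hi = csr_envelope(len(pts), UNIT_SQUARE, r, n_simulations=60,
                                 seed=seed)
            hits += bool((curve > hi).any())
        assert hits / n_seeds >= 0.95

    def test_envelope_seed_determinism(self):
        r = np.linspace(0.02, 0.1, 4)
        a = csr_envelope(50, UNIT_SQUARE, r, 30, seed=9)
        b = csr_envelope(50, UNIT_SQUARE, r, 30, seed=9)
        assert np.array_equal(a, b)

    def test_3d_dataset_rejected(self):
        ds = make_dataset([("f::1", 0, 0.0, 0.0, 0.0, 1.0),
                           ("f::1", 1, 1.0, 1.0, 0.0, 2.0)], dim=3)
        with pytest.raises(DimensionalityError):
            ripley_analysis(ds, np.array([1.0]))


class TestRoiDistance:
    def test_vertical_boundary_distance(self):
        roi = RoiGeometry.from_polygon(np.array([[100.0, 0.0], [100.0, 200.0]]))
        ds = make_dataset([("f::1", 0, 0.0, 40.0, 50.0), ("f::1", 1, 1.0, 100.0, 10.0)])
        out = distance_to_roi(ds, roi)
        assert out.spots[SPOT_DISTANCE_COLUMN].tolist() == [60.0, 0.0]

    def test_mask_matches_polygon_within_pixel(self):
        # straight vertical edge at x = 50 in a 100x100 image, 1 um pixels
        mask = np.zeros((100, 100), dtype=bool)
        mask[:, :50] = True
        roi_mask = RoiGeometry(mask=mask, pixel_size=1.0)
        roi_poly = RoiGeometry.from_polygon(np.array([[49.0, 0.0], [49.0, 99.0]]))
        rng = np.random.default_rng(3)
        x, y = rng.uniform(5, 95, 50), rng.uniform(5, 95, 50)
        assert np.abs(roi_mask.distance(x, y) - roi_poly.distance(x, y)).max() <= 1.0

    def test_translation_invariance(self):
        vertices = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0], [0.0, 0.0]])
        shift = np.array([123.0, -45.0])
        roi = RoiGeometry.from_polygon(vertices)
        roi_shifted = RoiGeometry.from_polygon(vertices + shift)
        rng = np.random.default_rng(4)
        pts = rng.uniform(-20, 30, (100, 2))
        d0 = roi.distance(pts[:, 0], pts[:, 1])
        d1 = roi_shifted.distance(pts[:, 0] + shift[0], pts[:, 1] + shift[1])
        assert np.abs(d0 - d1).max() < 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            RoiGeometry(mask=np.zeros((10, 10), dtype=bool))


class TestRoiTrackMetrics:
    @staticmethod
    def series_dataset(distances, dt=1.0):
        roi = RoiGeometry.from_polygon(np.array([[0.0, -100.0], [0.0, 100.0]]))
        ds = make_dataset([("f::1", i, i * dt, float(d), 0.0)
                           for i, d in enumerate(distances)])
        return roi_track_metrics(distance_to_roi(ds, roi)).tracks.iloc[0]

    def test_linear_approach_hand_values(self):
        row = self.series_dataset([10, 8, 6, 4])
        assert row["StartDistance_edge"] == 10.0
        assert row["EndDistance_edge"] == 4.0
        assert row["DirectionMovement_edge"] == -6.0
        assert row["AvgRateChange_edge"] == pytest.approx(-2.0)
        assert row["TrendSlope_edge"] == pytest.approx(-2.0)
        assert row["MedianDistance_edge"] == pytest.approx(7.0)
        assert row["PercentageChange_edge"] == pytest.approx(-60.0)

    def test_constant_distance(self):
        row = self.series_dataset([5, 5, 5])
        assert row["DirectionMovement_edge"] == 0.0
        assert row["TrendSlope_edge"] == pytest.approx(0.0, abs=1e-12)
        assert row["StdDevDistance_edge"] == 0.0

    def test_zero_start_guards_percentage(self):
        row = self.series_dataset([0, 2, 4])
        assert math.isnan(row["PercentageChange_edge"])
        assert np.isfinite(row["TrendSlope_edge"])

    def test_min_median_max_ordering(self):
        row = self.series_dataset([3, 9, 1, 7, 5])
        assert row["MinDistance_edge"] <= row["MedianDistance_edge"] <= row["MaxDistance_edge"]


class TestStratify:
    @staticmethod
    def with_max_distance(values):
        ds = make_dataset([(f"f::{i}", 0, 0.0, 0.0, 0.0) for i in range(len(values))])
        ds.tracks["MaxDistance_edge"] = values
        return stratify_by_distance(ds)

    def test_threshold_sides_and_boundary(self):
        out = self.with_max_distance([74.9, 75.0, 75.1])
        assert list(out.tracks["EDGE_STRATUM"]) == ["close", "close", "far"]

    def test_missing_column_is_error(self, small_scene):
        ds, _ = small_scene
        with pytest.raises(KeyError):
            stratify_by_distance(ds)


@pytest.fixture(scope="module")
def scene():
    spec = SceneSpec(conditions={"c": MotionModel(speed_mean=1.0, speed_sd=0.5,
                                                  n_frames=20)},
                     repeats=2, fovs_per_repeat=2, tracks_per_fov=15,
                     field_size=(500.0, 300.0), seed=13)
    ds, roi, truth = generate_roi_scene(spec, edge_x=60.0, approach_speed=2.0,
                                        fraction_approaching=0.5)
    ds = roi_track_metrics(distance_to_roi(ds, roi))
    return ds, truth


class TestRoiScene:
    def test_approaching_tracks_have_exact_slope(self, scene):
        ds, truth = scene
        tr = ds.tracks.set_index("unique_track_id")
        approaching = truth.loc[truth["approaching"], "unique_track_id"]
        assert np.abs(tr.loc[approaching, "TrendSlope_edge"] + 2.0).max() < 1e-9
        assert np.abs(tr.loc[approaching, "AvgRateChange_edge"] + 2.0).max() < 1e-9

    def test_direction_movement_is_end_minus_start(self, scene):
        ds, _ = scene
        tr = ds.tracks
        assert (tr["DirectionMovement_edge"]
                == tr["EndDistance_edge"] - tr["StartDistance_edge"]).all()

    def test_stratification_matches_ground_truth(self, scene):
        ds, truth = scene
        out = stratify_by_distance(ds, threshold=75.0)
        got = out.tracks.set_index("unique_track_id")["EDGE_STRATUM"]
        expected = truth.set_index("unique_track_id")["max_distance"].apply(
            lambda d: "close" if d <= 75.0 else "far")
        assert got.sort_index().equals(expected.sort_index())

    def test_wanderers_have_no_systematic_drift(self):
        spec = SceneSpec(conditions={"c": MotionModel(speed_mean=1.0, persistence=0.0,
                                                      n_frames=15)},
                         repeats=1, fovs_per_repeat=1, tracks_per_fov=200,
                         field_size=(600.0, 300.0), seed=17)
        ds, roi, truth = generate_roi_scene(spec, edge_x=60.0, fraction_approaching=0.0)
        ds = roi_track_metrics(distance_to_roi(ds, roi))
        mean_move = ds.tracks["DirectionMovement_edge"].mean()
        spread = ds.tracks["DirectionMovement_edge"].std()
        assert abs(mean_move) < 3 * spread / math.sqrt(len(ds.tracks))
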