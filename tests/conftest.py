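import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from celltracks import Dataset, MotionModel, SceneSpec, generate_dataset


def make_dataset(spot_records, track_ids=None, frame_interval=1.0, dim=2):
    """Small hand-built Dataset from (uid, frame, t, x, y[, z]) tuples."""
    cols = ["unique_track_id", "frame", "t", "x", "y"] + (["z"] if dim == 3 else [])
    spots = pd.DataFrame(spot_records, columns=cols)
    spots["file_name"] = "fov1"
    spots["condition"] = "A"
    spots["repeat"] = "R1"
    ids = track_ids or sorted(spots["unique_track_id"].unique())
    tracks = pd.DataFrame({"unique_track_id": ids, "file_name": "fov1",
                           "condition": "A", "repeat": "R1"})
    return Dataset(spots=spots, tracks=tracks, frame_interval=frame_interval,
                   dimensionality=dim)


@pytest.fixture
def triangle_track():
    """One 3-spot track tracing a 3-4-5 right triangle."""
    return make_dataset([
        ("fov1::1", 0, 0.0, 0.0, 0.0),
        ("fov1::1", 1, 1.0, 3.0, 0.0),
        ("fov1::1", 2, 2.0, 3.0, 4.0),
    ])


@pytest.fixture(scope="session")
def two_condition_scene():
    """Slow vs fast conditions, 2 repeats x 2 FOVs x 10 tracks each."""
    spec = SceneSpec(
        conditions={"slow": MotionModel(speed_mean=8.0, speed_sd=2.0, persistence=0.6),
                    "fast": MotionModel(speed_mean=16.0, speed_sd=2.0, persistence=0.6)},
        repeats=2, fovs_per_repeat=2, tracks_per_fov=10, seed=11,
        with_spot_features=True)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_scene():
    spec = SceneSpec(conditions={"ctrl": MotionModel(speed_mean=10.0)},
                     repeats=2, fovs_per_repeat=1, tracks_per_fov=5, seed=7)
    return generate_dataset(spec)
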