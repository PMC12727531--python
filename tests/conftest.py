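import numpy as np
import pytest

from ertrack.io_tracks import Localization, Trajectory, TrajectorySet


def make_trajectory(xy, track_id="0", dt=1.0, frames=None, intensity=None):
    """Build a Trajectory from an (n, 2) array of µm positions."""
    xy = np.asarray(xy, dtype=float)
    frames = range(len(xy)) if frames is None else frames
    pts = [
        Localization(t=f * dt, x=float(x), y=float(y), frame=int(f),
                     intensity=None if intensity is None else float(intensity[i]))
        for i, (f, (x, y)) in enumerate(zip(frames, xy))
    ]
    return Trajectory(track_id=track_id, points=pts)


def make_set(trajs, dt=1.0, pixel_size=0.1):
    return TrajectorySet(list(trajs), frame_interval=dt, pixel_size=pixel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def stationary_track():
    return make_trajectory(np.full((12, 2), 3.0))
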