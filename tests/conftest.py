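import numpy as np
import pandas as pd
import pytest

from shoalkit.trajectory import TrajectorySet, derive_velocities


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(positions_by_frame, fps=15.0):
    """Build a TrajectorySet from {frame: {id: (x, y, z)}}."""
    rows = []
    for frame, fish in positions_by_frame.items():
        for fid, (x, y, z) in fish.items():
            rows.append((frame, fid, x, y, z))
    df = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "z"])
    return TrajectorySet(df, fps=fps)


def trajectory_from_array(pos, fps=15.0):
    """(n_frames, n_ids, 3) array -> TrajectorySet with dense tracks."""
    T, n, _ = pos.shape
    frames = np.repeat(np.arange(T), n)
    ids = np.tile(np.arange(n), T)
    df = pd.DataFrame(
        {"frame": frames, "id": ids,
         "x": pos[:, :, 0].ravel(), "y": pos[:, :, 1].ravel(), "z": pos[:, :, 2].ravel()}
    )
    return TrajectorySet(df, fps=fps)


def correlated_steps(rng, T, n, a=0.9, scale=2.0):
    """AR(1)-correlated step sequence: headings decorrelate over ~1/(1-a) frames."""
    steps = np.empty((T, n, 3))
    steps[0] = rng.normal(scale=scale, size=(n, 3))
    for k in range(1, T):
        steps[k] = a * steps[k - 1] + rng.normal(scale=scale * np.sqrt(1 - a**2), size=(n, 3))
    return steps


@pytest.fixture
def random_walk_traj(rng):
    pos = np.cumsum(correlated_steps(rng, 40, 6), axis=0) + 100.0
    return trajectory_from_array(pos)


@pytest.fixture
def random_walk_velocities(random_walk_traj):
    return derive_velocities(random_walk_traj)
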