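import numpy as np
import pytest

from dermtrack.track_io import Track, TrackPoint


def make_track(positions, dt=60.0, track_id="t0", metadata=None, frames=None):
    """Build a Track from an (n, 3)-like position list at uniform dt seconds."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[1] == 2:
        positions = np.hstack([positions, np.zeros((len(positions), 1))])
    if frames is None:
        frames = range(len(positions))
    points = [
        TrackPoint(frame=int(f), t=float(f) * dt, x=float(p[0]), y=float(p[1]),
                   z=float(p[2]))
        for f, p in zip(frames, positions)
    ]
    return Track(track_id=track_id, points=points, metadata=dict(metadata or {}))


def random_track(rng, n_points=20, scale=5.0, track_id="r0", metadata=None):
    """A seeded random 3D walk track with uniform 60-s frame spacing."""
    steps = rng.normal(0, scale, size=(n_points - 1, 3))
    positions = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)]) + 100.0
    return make_track(positions, track_id=track_id, metadata=metadata)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
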