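import numpy as np
import pytest

from gcclutch import SimConfig, Track, TrackSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return SimConfig()


def make_brownian_track(rng, D=0.05, dt=0.05, n=20, track_id=0):
    """Pure 2D Brownian track with diffusion coefficient D."""
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n - 1, 2))
    p = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Track(track_id, np.arange(n) * dt, p[:, 0], p[:, 1], dt)


def make_linear_track(v=(0.1, 0.0), dt=0.5, n=20, track_id=0):
    """Uniform-motion track x = v·t."""
    t = np.arange(n) * dt
    return Track(track_id, t, v[0] * t, v[1] * t, dt)


def make_trackset(tracks, dt):
    return TrackSet(list(tracks), dt)
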