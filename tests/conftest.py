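import numpy as np
import pytest

from tcellmech import Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(points, dt=5.0, track_id="t"):
    """Track from a list of (x, y) points at uniform dt."""
    pts = np.asarray(points, dtype=float)
    times = np.arange(len(pts)) * dt
    return Track(track_id=track_id, times=times, xs=pts[:, 0], ys=pts[:, 1])


def random_track(rng, n_points=None, scale=20.0, dt=5.0, track_id="rand"):
    """Random-walk track with up to 50 points."""
    if n_points is None:
        n_points = int(rng.integers(2, 51))
    steps = rng.normal(0.0, scale / 10.0, (n_points - 1, 2))
    pts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return make_track(pts, dt=dt, track_id=track_id)


def brute_force_max_excursion(track):
    """O(n²) oracle: explicit double loop over all point pairs."""
    pts = track.positions
    best = 0.0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = float(np.hypot(*(pts[i] - pts[j])))
            if d > best:
                best = d
    return best
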