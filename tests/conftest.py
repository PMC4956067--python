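import numpy as np
import pytest

from skillmatch.skeleton import N_JOINTS, SkeletonStream, TrackingState
from skillmatch.synthetic import _base_positions


@pytest.fixture
def idle_stream():
    """60 s of neutral stance with 5 mm Gaussian sway (no events)."""
    rng = np.random.default_rng(123)
    n = 60 * 30
    t = np.arange(n) / 30.0
    pos = _base_positions()[None] + rng.normal(0.0, 0.005, size=(n, N_JOINTS, 3))
    states = np.full((n, N_JOINTS), int(TrackingState.TRACKED), dtype=np.uint8)
    orients = np.zeros((n, N_JOINTS, 3), dtype=np.float32)
    return SkeletonStream(t, pos.astype(np.float32), states, orients, nominal_rate=30.0)


def make_linear_stream(values, joint, axis, rate=30.0):
    """Stream whose given joint/axis follows `values`; everything else static."""
    n = len(values)
    t = np.arange(n) / rate
    pos = np.tile(_base_positions()[None], (n, 1, 1))
    pos[:, int(joint), axis] += np.asarray(values, dtype=float)
    states = np.full((n, N_JOINTS), int(TrackingState.TRACKED), dtype=np.uint8)
    orients = np.zeros((n, N_JOINTS, 3), dtype=np.float32)
    return SkeletonStream(t, pos.astype(np.float32), states, orients, nominal_rate=rate)
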