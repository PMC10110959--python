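import numpy as np
import pytest

from modewalk import DEFAULT_MODE_PARAMS, Trajectory, fixture, synthetic


def make_trajectory(positions, track_id="t", dt=1.0, condition=None):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(positions.shape[0], dtype=float) * dt
    return Trajectory(track_id=track_id, times=times, positions=positions,
                      condition=condition)


@pytest.fixture
def ballistic():
    return fixture("ballistic", {"speed": 2.0, "n_points": 61})


@pytest.fixture
def circle60():
    return fixture("circle", {"n_points": 60})


@pytest.fixture
def zigzag60():
    return fixture("zigzag", {"n_points": 60})


def mode_segments(mode, n, seed_base=0, n_steps=60):
    """n constant-mode 60-point segments with independent streams."""
    params = DEFAULT_MODE_PARAMS[mode]
    return [synthetic.simulate_mode_segment(params, n_steps, seed=seed_base * 100_000 + i)
            for i in range(n)]
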