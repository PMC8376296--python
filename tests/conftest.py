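import numpy as np
import pytest

from vpvigor import SimulationConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A 15-min synthetic session with a small neuron population."""
    cfg = SimulationConfig(duration_s=900.0, n_neurons=10, frac_excited=0.6)
    bundle, truth = generate_session(cfg, seed=5)
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_pose(x, y=None, frame_rate=30.0, valid=None):
    """Build a PoseSeries from coordinate arrays (heading along +x)."""
    from vpvigor import PoseSeries

    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    pos = np.column_stack([x, y])
    if valid is None:
        valid = np.isfinite(pos).all(axis=1)
    heading = np.zeros(len(x))
    return PoseSeries(position=pos, heading=heading, valid=np.asarray(valid, bool), frame_rate=frame_rate)
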