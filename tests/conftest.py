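import numpy as np
import pytest

from gaitsim import GaitScenario, generate_scenario
from gaitsim.evaluation import participant_from_scenario
from gaitsim.kinematics_io import SensorTrajectory


@pytest.fixture(scope="session")
def scenario20():
    """Noise-free symmetric 20-stride scenario (seed 7)."""
    return generate_scenario(GaitScenario(seed=7, n_strides=20))


@pytest.fixture(scope="session")
def scenario_small():
    """Short 8-stride scenario for cheap unit tests."""
    return generate_scenario(GaitScenario(seed=3, n_strides=8))


@pytest.fixture(scope="session")
def participant_vd(scenario20):
    """Bilateral signals at the ventral (S1) and dorsal (S9) slots of ring 1
    on both leg segment types."""
    keys = [("lower_leg", 1, 1), ("lower_leg", 1, 9),
            ("upper_leg", 1, 1), ("upper_leg", 1, 9)]
    return participant_from_scenario(scenario20, keys)


@pytest.fixture(scope="session")
def shank_pair(participant_vd):
    """The ventral lower-leg sensor pair of the default scenario."""
    return participant_vd.sensors[0]


def rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    Q = np.zeros(np.shape(theta) + (3, 3))
    Q[..., 0, 0] = c
    Q[..., 0, 1] = s
    Q[..., 1, 0] = -s
    Q[..., 1, 1] = c
    Q[..., 2, 2] = 1.0
    return Q


@pytest.fixture
def make_spinning_sensor():
    """Factory: sensor trajectory rotating about global z at a constant rate."""

    def _make(rate=1.0, fs=100.0, duration=2.0, k=None):
        t = np.arange(0.0, duration, 1.0 / fs)
        Q = rotation_z(rate * t)
        if k is None:
            k = np.zeros((len(t), 3))
        return SensorTrajectory(t=t, k=k, Q_s=Q, fs=fs)

    return _make
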