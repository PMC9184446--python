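import numpy as np
import pytest

from emdtcn.synth import SyntheticConfig, generate_trajectory
from emdtcn.trajectory import Trajectory


@pytest.fixture(scope="session")
def breathing_traj():
    """Default-condition synthetic breathing record (2,000 samples)."""
    return generate_trajectory(SyntheticConfig(duration_samples=2000, seed=0))


@pytest.fixture(scope="session")
def two_tone():
    """0.25 Hz + 2 Hz tones at 26 Hz: a well-separated pair for EMD checks."""
    fs = 26.0
    t = np.arange(4000) / fs
    slow = 10.0 * np.sin(2 * np.pi * 0.25 * t)
    fast = 1.5 * np.sin(2 * np.pi * 2.0 * t)
    return {
        "traj": Trajectory(slow + fast, fs=fs, id="two-tone"),
        "slow": slow,
        "fast": fast,
        "fs": fs,
    }
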