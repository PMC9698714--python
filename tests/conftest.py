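import numpy as np
import pytest

from oegait import preset_config, simulate_gait
from oegait.pipeline import RunConfig, analyze_recording


@pytest.fixture(scope="session")
def normal_sim():
    """Normal-gait preset recording with its ground truth."""
    cfg = preset_config("normal")
    rec, truth = simulate_gait(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    """Normal preset without noise or drift: closed forms hold tightly."""
    cfg = preset_config("normal", noise_sigma=0.0, drift_rate=0.0)
    rec, truth = simulate_gait(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def normal_report(normal_sim):
    _, rec, _ = normal_sim
    return analyze_recording(rec, RunConfig())


@pytest.fixture(scope="session")
def noiseless_report(noiseless_sim):
    _, rec, _ = noiseless_sim
    return analyze_recording(rec, RunConfig())


@pytest.fixture
def static_recording():
    """10 s of pure standing at 100 Hz (gravity on z, no motion)."""
    from oegait import ImuRecording

    n = 1000
    t = np.arange(n) / 100.0
    accel = np.zeros((n, 3))
    accel[:, 2] = 9.81
    return ImuRecording(timestamps=t, accel_sensor=accel, nominal_rate=100.0)
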