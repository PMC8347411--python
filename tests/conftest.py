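import numpy as np
import pytest
from hypothesis import settings

import rpmgait as rg

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_gait():
    """Noise-free 60 s bilateral session, 100 steps/limb, with truth."""
    params = rg.GaitParams(cadence=100, duration=60, noise_sd=0.0, seed=11)
    op, nonop, truth = rg.generate_gait_session(params)
    return params, op, nonop, truth


@pytest.fixture(scope="session")
def noisy_gait():
    """Default-noise 60 s bilateral session with configured asymmetry 0.8."""
    params = rg.GaitParams(cadence=100, duration=60, asymmetry_factor=0.8, seed=12)
    op, nonop, truth = rg.generate_gait_session(params)
    return params, op, nonop, truth


@pytest.fixture(scope="session")
def flexion_data():
    """Noise-free flexion dataset: 4 sensors + 100 Hz ground-truth trace."""
    params = rg.FlexionSimParams(noise_sd=0.0, seed=21)
    sensors, trace = rg.generate_flexion_dataset(params)
    return params, sensors, trace


@pytest.fixture(scope="session")
def flexion_model(flexion_data):
    """Surrogate trained on the first 75% of the flexion dataset."""
    _, sensors, trace = flexion_data
    ts = rg.build_training_set(sensors, trace, hop=0.25)
    train, holdout = ts.split(0.25)
    model = rg.train_surrogate(train, seed=21)
    return model, train, holdout


def constant_session(value=(0.0, 0.0, 1.0), n=2298, fs=1149.0):
    ax, ay, az = value
    zeros = np.zeros(n)
    return rg.ImuSession(
        channels={
            "ax": np.full(n, ax),
            "ay": np.full(n, ay),
            "az": np.full(n, az),
            "gx": zeros,
            "gy": zeros,
            "gz": zeros,
        },
        sample_rate=fs,
    )
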