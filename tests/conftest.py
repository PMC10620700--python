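import dataclasses

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import oddballerp as ob


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def oddball_sequence():
    """A standard 64-target / 256-standard sequence."""
    return ob.generate_stimulus_sequence(64, 256, (900, 1100), seed=1)


@pytest.fixture(scope="session")
def cn_params():
    return ob.simulate_subject_params("CN", seed=7)


@pytest.fixture(scope="session")
def noiseless_params(cn_params):
    """Deterministic subject: no noise, perfect behavior, 8 µV P300 at 400 ms."""
    return dataclasses.replace(
        cn_params,
        noise_sd_uv=0.0, alpha_power=0.0,
        hit_rate=1.0, commission_rate=0.0,
        p300_amplitude_uv=8.0, p300_latency_ms=400.0, p300_width_ms=40.0,
    )


@pytest.fixture(scope="session")
def noiseless_recording(oddball_sequence, noiseless_params):
    return ob.synthesize_session(oddball_sequence, noiseless_params, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30+15-subject simulated cohort table with its exclusion ledger."""
    return ob.simulate_cohort_table(30, 15, seed=5)


def gaussian_bump_wave(amplitude=5.0, center_ms=400.0, sigma_ms=40.0, offset=0.0):
    """A difference-wave-shaped test signal on the epoch axis."""
    t = ob.erp.epoch_times()
    return amplitude * np.exp(-((t - center_ms) ** 2) / (2 * sigma_ms ** 2)) + offset
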