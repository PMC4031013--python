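import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nwistrat.simulate import WaveformParams, calibrate_params, generate_waveform

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def noiseless_params() -> WaveformParams:
    """Clean six-beat waveform at HR 75 (period 0.8 s, 160 samples)."""
    return WaveformParams(heart_rate=75.0, n_beats=6,
                          noise_sd_displacement=0.0, noise_sd_velocity=0.0)


@pytest.fixture
def noiseless_recording(noiseless_params):
    return generate_waveform(noiseless_params, seed=0)


@pytest.fixture
def calibrated_clean_recording():
    """Noiseless recording whose analyzed peaks are exactly 5400/1900.

    HR 75 makes the beat period an integer number of 5 ms samples, so all
    beats are sample-aligned and bitwise identical.
    """
    params = calibrate_params(5400.0, 1900.0, heart_rate=75.0)
    clean = dataclasses.replace(params, noise_sd_displacement=0.0,
                                noise_sd_velocity=0.0)
    return generate_waveform(clean, seed=0)
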