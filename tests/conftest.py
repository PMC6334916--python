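import logging

import numpy as np
import pandas as pd
import pytest

import moodscreen as ms

logging.getLogger("moodscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def static_recording():
    """5 s at rest: accel (0,0,1) g, zero gyro, 300 Hz."""
    n = 1500
    t = np.arange(n) / 300.0
    accel = np.tile([0.0, 0.0, 1.0], (n, 1))
    gyro = np.zeros((n, 3))
    return ms.ImuRecording(time=t, accel=accel, gyro=gyro, sample_rate_hz=300.0)


@pytest.fixture(scope="session")
def small_table():
    """12-subject feature table with a mild planted effect."""
    return ms.simulate_feature_table(
        5, 7, 20, effects={"f000": 2.0}, seed=42
    )


@pytest.fixture(scope="session")
def noise_free_case_channels():
    """Zero-noise case subject pushed through the full front end."""
    spec = ms.CohortSpec(accel_noise_g=0.0, gyro_noise_dps=0.0,
                         sway_amp_deg=0.0, jolt_amp_g=0.0)
    rec, startle = ms.simulate_subject("case", spec, 7)
    return ms.process_recording(rec), startle, spec
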