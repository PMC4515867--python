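"""Shared fixtures: small synthetic recordings and cohorts.

Signal fixtures default to 10 Hz to keep the unit suite fast; every
operator is sampling-rate parametric, and full-rate behaviour is covered
by the end-to-end recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from actimet.accelerometry import RawRecording
from actimet.synthetic import CohortParams, SignalProfile, generate_cohort, \
    generate_raw_recording


@pytest.fixture(scope="session")
def clean_profile() -> SignalProfile:
    """Noise-free, perfectly calibrated, no bouts/nonwear."""
    return SignalProfile(days=3, sampling_rate_hz=10.0, noise_sd_g=0.0,
                         background_enmo_mg=30.0, seed=11)


@pytest.fixture(scope="session")
def clean_recording(clean_profile):
    return generate_raw_recording(clean_profile)


@pytest.fixture(scope="session")
def busy_profile() -> SignalProfile:
    """Bouts + nonwear + miscalibration + noise; 8 days at 10 Hz."""
    return SignalProfile(
        days=8, sampling_rate_hz=10.0, seed=5,
        mvpa_bouts=((1, 10.0, 30.0, 150.0), (3, 15.0, 20.0, 130.0),
                    (5, 9.0, 12.0, 180.0)),
        nonwear_intervals=((2, 17.0, 180.0), (6, 11.0, 120.0)),
        axis_gain=(1.02, 0.99, 1.005),
        axis_offset_g=(0.01, -0.008, 0.004),
    )


@pytest.fixture(scope="session")
def busy_recording(busy_profile):
    return generate_raw_recording(busy_profile)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortParams(n=500, seed=21))


def make_recording(xyz: np.ndarray, fs: float, start_s: float = 0.0,
                   weekday: int = 0) -> RawRecording:
    return RawRecording(np.asarray(xyz, dtype=np.float64), fs, start_s, weekday)


def constant_recording(vector, days: float, fs: float = 1.0,
                       start_s: float = 0.0) -> RawRecording:
    n = int(round(days * 86400 * fs))
    xyz = np.tile(np.asarray(vector, dtype=np.float64), (n, 1))
    return make_recording(xyz, fs, start_s)
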