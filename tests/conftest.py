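"""Shared fixtures: small synthetic sessions sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

import fmdetect as fd


@pytest.fixture(scope="session")
def small_config() -> fd.SessionConfig:
    """A 120 s session with the default event density, fixed seed."""
    return fd.SessionConfig(duration_s=120.0, seed=42, scan_id="scanA")


@pytest.fixture(scope="session")
def small_session(small_config):
    return fd.generate_recording(small_config)


@pytest.fixture(scope="session")
def clean_session(small_session):
    """The small session after the full preprocessing chain."""
    recording, track = small_session
    return fd.preprocess_pipeline(recording, track)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
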