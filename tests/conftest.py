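"""Shared fixtures.

The two full phantom studies are expensive (minutes each), so they run
once per session and are shared between the workflow tests and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from ra223spect import load_default_model
from ra223spect.studies import StudyConfig, run_study_a, run_study_b


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture(scope="session")
def study_a_report():
    """Full cylinder-phantom study: 2 collimators x 4 windows, 10 slices."""
    return run_study_a(StudyConfig(seed=1, n_replicates=10))


@pytest.fixture(scope="session")
def study_b_report():
    """Full body-phantom study: 5 noise replicates per collimator plus the
    three-level linearity series."""
    return run_study_b(StudyConfig(seed=1, n_replicates=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
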