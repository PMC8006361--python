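"""Shared fixtures: all data are generated programmatically at test time."""

import numpy as np
import pytest

from cmrperf.synthetic import (
    BolusParams,
    StudyConfig,
    gamma_variate_aif,
    noiseless_config,
    simulate_study,
)


@pytest.fixture(scope="session")
def clean_aif():
    """Single-pass bolus (no recirculation) on a uniform 0.5 s grid,
    onset at t=0 — the standard input for deconvolution unit tests."""
    t = np.arange(0.0, 20.0001, 0.5)
    return gamma_variate_aif(BolusParams(onset_time=0.0, recirc_fraction=0.0), t)


@pytest.fixture(scope="session")
def small_noiseless_study():
    """Two-patient noiseless study with identity location effects."""
    return simulate_study(noiseless_config(n_patients=2, seed=42))


@pytest.fixture(scope="session")
def paper_scale_study():
    """Full 25-patient study under default (calibrated) conditions."""
    return simulate_study(StudyConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
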