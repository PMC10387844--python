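"""Shared fixtures: seeded synthetic spectrum pairs reused across tests."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

import ftirquant as fq

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_cisplatin_pair():
    """Noiseless, jitter-free control/treated groups (n = 1) from the
    cisplatin preset: every planted value is exactly recoverable."""
    model, effect = fq.preset_pair("cisplatin", seed=11)
    model = replace(model, noise_sd=0.0)
    effect = replace(effect, replicate_cv=0.0, position_jitter_sd=0.0)
    return fq.simulate_group_pair(model, effect, n_per_group=1, seed=11)


@pytest.fixture(scope="session")
def noiseless_control_spectrum(noiseless_cisplatin_pair):
    return noiseless_cisplatin_pair[0].replicates[0]


@pytest.fixture()
def gaussian_spectrum():
    """Single unit-apex Gaussian band at 2924 cm^-1 on a zero baseline."""
    grid = np.arange(2700.0, 3200.0, 4.0)
    fwhm = 15.0
    trace = np.exp(-4 * np.log(2) * ((grid - 2924.0) / fwhm) ** 2)
    return fq.Spectrum("gauss", "", grid, trace)
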