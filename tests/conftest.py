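"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

from carotidseg import phantom


@pytest.fixture(scope="session")
def clean_spec():
    """Default-geometry phantom with no blur and no noise (analytic truth)."""
    return phantom.PhantomSpec(noise_sd=0.0, blur_sigma_mm=0.0)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    """(volume, truth labels, centerline model) for the clean default spec."""
    vol, labels, model = phantom.generate_phantom(clean_spec)
    return vol, labels, model


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default spec with its documented blur and noise."""
    spec = phantom.PhantomSpec(seed=11)
    vol, labels, model = phantom.generate_phantom(spec)
    return spec, vol, labels, model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
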