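import numpy as np
import pytest

from sngfr import default_spec, render_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless straight-tube phantom at the study-condition flow (1.7 nl/min)."""
    spec = default_spec(flow_nl_min=1.7, noise_sigma=0.0, seed=0)
    series, volumes, roi, truth = render_phantom(spec)
    return spec, series, volumes, roi, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same geometry with 5% Gaussian noise."""
    spec = default_spec(flow_nl_min=1.7, noise_sigma=0.05, seed=7)
    series, volumes, roi, truth = render_phantom(spec)
    return spec, series, volumes, roi, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
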