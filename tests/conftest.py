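import numpy as np
import pytest

from cnnrf import (
    GaborParams,
    make_white_noise_stimuli,
    sample_cell,
    simulate_responses,
)


@pytest.fixture(scope="session")
def small_stimuli():
    """200 white-noise stimuli at 10x10 for cheap model tests."""
    return make_white_noise_stimuli(200, size=10, seed=123)


@pytest.fixture(scope="session")
def medium_stimuli():
    """500 white-noise stimuli at 10x10 (for linear-RF and baseline tests)."""
    return make_white_noise_stimuli(500, size=10, seed=321)


@pytest.fixture
def example_gabor():
    """A well-behaved in-bounds Gabor parameter set on a 10x10 field."""
    return GaborParams(A=1.0, sigma1=1.5, sigma2=1.8, k0=1.8, tau=0.7, x0=4.5, y0=5.5, theta=0.9)


@pytest.fixture(scope="session")
def simple_cell_noiseless(medium_stimuli):
    """A noiseless simulated simple cell and its responses."""
    spec = sample_cell("simple", seed=7)
    spec.noise_sd = 0.0
    resp = simulate_responses(spec, medium_stimuli, seed=8)
    return spec, resp
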