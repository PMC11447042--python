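import numpy as np
import pytest

from ratiospec import (
    DEFAULT_CONFIGS,
    component_spectrum,
    default_profiles,
    ratio_spectrum,
)
from ratiospec.pipeline import divisor_for


@pytest.fixture(scope="session")
def profiles():
    """(bpl_like, tst_like) bundled component profiles."""
    return default_profiles()


@pytest.fixture(scope="session")
def grid():
    return np.linspace(200.0, 400.0, 201)


@pytest.fixture(scope="session")
def configs():
    return dict(DEFAULT_CONFIGS)


@pytest.fixture(scope="session")
def divisors(configs):
    """Noise-free divisor spectrum for each bundled method config."""
    return {name: divisor_for(cfg) for name, cfg in configs.items()}


@pytest.fixture
def bpl_ratio(profiles, divisors):
    """Ratio spectrum of a 10 ug/mL BPL-like standard over the TST divisor."""
    bpl, _ = profiles
    sample = component_spectrum(bpl, 10.0)
    return ratio_spectrum(sample, divisors["BPL-RD"])


def make_linear_ratio(slope, intercept, lo=200.0, hi=300.0, step=1.0):
    """A ratio spectrum whose amplitude is an exact linear ramp in nm."""
    from ratiospec import RatioSpectrum

    w = np.arange(lo, hi + step / 2, step)
    return RatioSpectrum(w, slope * w + intercept, "synthetic")
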