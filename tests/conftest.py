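import numpy as np
import pytest

from actloc.frontend import ErbBank, build_template
from actloc.geometry import make_direction_grid
from actloc.synth import (
    SphericalHeadParams,
    fit_source_prior,
    synth_hrir_set,
    synth_source_corpus,
)


@pytest.fixture(scope="session")
def bank48():
    return ErbBank(fs=48000.0)


@pytest.fixture(scope="session")
def small_grid():
    """A 300-direction grid: coarse but fast for observer-level tests."""
    return make_direction_grid(300)


@pytest.fixture(scope="session")
def head_params():
    return SphericalHeadParams()


@pytest.fixture(scope="session")
def small_template(small_grid, head_params, bank48):
    hrirs = synth_hrir_set(small_grid, head_params, fs=48000.0, length=256)
    return build_template(hrirs, small_grid, bank48)


@pytest.fixture(scope="session")
def source_prior(bank48):
    return fit_source_prior(synth_source_corpus(seed=0, cfs=bank48.cfs))


@pytest.fixture(scope="session")
def flat_spectrum(bank48):
    return np.zeros(bank48.n_channels)
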