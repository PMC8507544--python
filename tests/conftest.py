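import dataclasses

import numpy as np
import pytest

from cytoscreen.phantom import (
    CameraModel,
    SpectralPhantomParams,
    default_axis,
)
from cytoscreen.spectral_core import SpectrumSet, WavenumberAxis


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def small_axis():
    return WavenumberAxis(np.linspace(600.0, 1800.0, 200))


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def phantom_params():
    return SpectralPhantomParams()


@pytest.fixture(scope="session")
def clean_params(phantom_params):
    """Spectral phantom without cosmic rays (other variability kept)."""
    return dataclasses.replace(phantom_params, cosmic_ray_rate=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210921)


def random_spectrum_set(rng, n=5, p=50, lo=600.0, hi=1800.0):
    axis = WavenumberAxis(np.sort(rng.uniform(lo, hi, size=p)))
    return SpectrumSet(axis=axis, matrix=rng.normal(100.0, 10.0, size=(n, p)))
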