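import numpy as np
import pytest

from walinet.axis import AXIS_3D, SpectralAxis
from walinet.nuisance import NuisanceParams, assemble_training_set
from walinet.spin_sim import build_basis, load_catalog


@pytest.fixture(scope="session")
def axis():
    """Default 3D acquisition grid (453 points, 2326 Hz, 7T)."""
    return AXIS_3D


@pytest.fixture(scope="session")
def fine_axis():
    """High-resolution axis for sub-Hz frequency measurements."""
    return SpectralAxis(n_points=32768, bandwidth_hz=2326.0)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def basis(catalog, axis):
    systems, _ = catalog
    return build_basis(systems, axis)


@pytest.fixture(scope="session")
def rel_conc(catalog):
    return catalog[1]


@pytest.fixture(scope="session")
def small_dataset(basis, rel_conc):
    """120 spectra from 4 synthetic subjects, water included."""
    return assemble_training_set(
        120, "walinet", basis, rel_conc, n_subjects=4, seed=7
    )


@pytest.fixture(scope="session")
def nuisance_params():
    return NuisanceParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
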