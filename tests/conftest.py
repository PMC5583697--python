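import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pwsnano import SpectralAxis, SpectralCube, default_axis

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def axis200() -> SpectralAxis:
    """The standard acquisition grid: 200 wavelengths, 500..699 nm."""
    return default_axis()


@pytest.fixture(scope="session")
def axis_small() -> SpectralAxis:
    """Coarser 100-point grid (2 nm spacing) for cheap cube fixtures."""
    return SpectralAxis(np.arange(500.0, 700.0, 2.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_cube(spectra: np.ndarray, axis: SpectralAxis, pixel_size_um: float = 1.0) -> SpectralCube:
    """Cube from an (n_pixels, n_wl) spectra matrix laid out as an (n, 1) image."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    return SpectralCube(spectra[:, None, :], axis, pixel_size_um)
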