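import numpy as np
import pytest

import wavekit as wk


def rel_l2(a, b):
    a, b = np.asarray(a), np.asarray(b)
    return np.linalg.norm((a - b).ravel()) / max(np.linalg.norm(b.ravel()), 1e-300)


@pytest.fixture
def mono_spectrum():
    return wk.Spectrum.monochromatic(0.5)


@pytest.fixture
def grid64():
    return wk.SamplingGrid(64, 64, 1.0, 1.0)


@pytest.fixture
def gaussian_field():
    """Compact Gaussian beam (w0 = 10 µm) on a 256² raster, λ = 0.5 µm."""
    grid = wk.SamplingGrid(256, 256, 1.0, 1.0)
    spectrum = wk.Spectrum.monochromatic(0.5)
    y, x = grid.coords()
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    u = np.exp(-r2 / 10.0 ** 2)
    return wk.Field(u=u[None], grid=grid, spectrum=spectrum)


@pytest.fixture
def strong_seidel():
    """Strong Seidel aberrations of a miniature widefield microscope (waves)."""
    return wk.SeidelSpec((0.85, 0.56, 0.25, 0.29, 0.0))


@pytest.fixture
def radial_psfs_64(strong_seidel):
    """Radially sampled aberrated PSFs covering a 64×64 field of view."""
    patch = wk.SamplingGrid(64, 64, 1.0, 1.0)
    fov_radius = float(np.hypot(32, 32))
    radii = np.arange(0.0, np.ceil(np.sqrt(2) * 32) + 2, 2.0)
    return wk.radial_psf_line(strong_seidel, patch, 0.05, 0.55, radii,
                              fov_radius)


@pytest.fixture
def sparse_points_64():
    """Ten seeded point sources on a 64×64 raster."""
    rng = np.random.default_rng(0)
    s = np.zeros((64, 64))
    idx = rng.choice(64 * 64, 10, replace=False)
    s.ravel()[idx] = rng.uniform(0.5, 1.0, 10)
    return s
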