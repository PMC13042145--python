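"""Incoherent image formation: 4f PSF stacks and planewise convolution.

The coherent PSF of a 4f system is the inverse Fourier transform of its
pupil (aperture disk times aberration phase times paraxial defocus);
incoherent imaging of a fluorescent volume is the sum over planes of the
sample intensity convolved with the intensity PSF of that plane.  All
convolutions are linear (zero-padded), never circular — physical image
formation has no wrap-around.

The private ``_conv_same``/``_conv_same_adjoint`` pair implements the
linear convolution with "same" cropping and its exact adjoints with
respect to either argument; inverse drivers backpropagate through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .field import SamplingGrid, Spectrum
from .elements import pupil_coords

__all__ = [
    "PSFStack",
    "simulate_psf_stack_4f",
    "incoherent_image_2d",
    "incoherent_image_3d",
]


# ---------------------------------------------------------------------------
# linear convolution with exact adjoints


def _conv_same(sample: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Linear (zero-padded) n-D convolution cropped to the sample shape.

    The crop offset is ``kernel.shape // 2`` per axis, so a unit impulse
    at the sample's central index ``n // 2`` reproduces the kernel
    exactly when shapes match.
    """
    full = [s + k - 1 for s, k in zip(sample.shape, kernel.shape)]
    fast = [sp_fft.next_fast_len(n) for n in full]
    F = sp_fft.rfftn(sample, fast) * sp_fft.rfftn(kernel, fast)
    out = sp_fft.irfftn(F, fast)
    sl = tuple(slice(k // 2, k // 2 + s) for s, k in zip(sample.shape, kernel.shape))
    return np.ascontiguousarray(out[sl])


def _conv_same_adjoint(g: np.ndarray, fixed: np.ndarray,
                       out_shape: tuple[int, ...],
                       kernel_shape: tuple[int, ...]) -> np.ndarray:
    """Adjoint of ``_conv_same`` w.r.t. one argument.

    ``g`` is the cotangent on the output (sample shape), ``fixed`` the
    argument held constant, ``out_shape`` the shape of the argument being
    differentiated, and ``kernel_shape`` the kernel shape used in the
    forward pass (it fixes the crop offset).  Computes
    ``d[j] = Σ_q g[q] · fixed[q + off − j]`` with ``off = kernel_shape // 2``.
    """
    full = [a + b - 1 for a, b in zip(g.shape, fixed.shape)]
    fast = [sp_fft.next_fast_len(n) for n in full]
    # cross-correlation C[m] = Σ_q g[q] fixed[q + m], negative lags wrap
    C = sp_fft.irfftn(np.conj(sp_fft.rfftn(g, fast)) * sp_fft.rfftn(fixed, fast),
                      fast)
    idx = [(k // 2 - np.arange(n)) % f
           for k, n, f in zip(kernel_shape, out_shape, fast)]
    return np.ascontiguousarray(C[np.ix_(*idx)])


# ---------------------------------------------------------------------------
# PSF stacks


@dataclass(frozen=True)
class PSFStack:
    """Intensity PSF pages over axial planes."""

    pages: np.ndarray  # (nz, ny, nx), nonnegative
    z_planes: tuple[float, ...]
    grid: SamplingGrid

    def __post_init__(self):
        pages = np.asarray(self.pages, dtype=float)
        if pages.ndim != 3:
            raise ValueError("pages must be (nz, ny, nx)")
        zs = tuple(float(z) for z in np.atleast_1d(self.z_planes))
        if pages.shape[0] != len(zs):
            raise ValueError("page count must equal z-plane count")
        if pages.shape[1:] != self.grid.shape:
            raise ValueError("pages must match the grid shape")
        if np.any(pages < -1e-12 * max(pages.max(initial=0.0), 1.0)):
            raise ValueError("PSF pages must be nonnegative")
        object.__setattr__(self, "pages", pages)
        object.__setattr__(self, "z_planes", zs)

    @property
    def nz(self) -> int:
        return self.pages.shape[0]

    def z_spacing(self) -> float:
        """Uniform plane spacing; raises if planes are not equispaced."""
        if len(self.z_planes) < 2:
            return 0.0
        d = np.diff(self.z_planes)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise ValueError("z planes are not uniformly spaced")
        return float(d[0])


def _centered_ifft2(page: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(page)))


def pupil_disk(grid: SamplingGrid, na: float, wavelength: float) -> np.ndarray:
    """Binary aperture on the centered frequency raster (ρ ≤ 1)."""
    coords = pupil_coords(grid, na, wavelength)
    return (coords.rho <= 1.0).astype(float)


def defocus_phase(grid: SamplingGrid, wavelength_medium: float, z: float) -> np.ndarray:
    """Paraxial defocus pupil phase ``-π λ z (fx²+fy²)`` (radians, centered)."""
    dy, dx = grid.pitch(0)
    fy = np.fft.fftshift(np.fft.fftfreq(grid.ny, d=dy))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(grid.nx, d=dx))[None, :]
    return -np.pi * wavelength_medium * z * (fy ** 2 + fx ** 2)


def coherent_psf_page(grid: SamplingGrid, na: float, wavelength: float,
                      n_medium: float, aberration: np.ndarray | None,
                      z: float) -> np.ndarray:
    """Complex amplitude PSF for one wavelength at defocus z (centered)."""
    disk = pupil_disk(grid, na, wavelength)
    if not disk.any():
        raise ValueError("aperture contains no pupil samples at this NA/raster")
    phase = defocus_phase(grid, wavelength / n_medium, z)
    if aberration is not None:
        phase = phase + aberration
    return _centered_ifft2(disk * np.exp(1j * phase))


def simulate_psf_stack_4f(na: float, aberration: np.ndarray | None,
                          z_planes, grid: SamplingGrid, spectrum: Spectrum,
                          ) -> PSFStack:
    """Aberrated incoherent PSF stack of a 4f system.

    ``aberration`` is a pupil phase map in radians on the centered
    frequency raster of ``grid`` (shape (ny, nx), shared across
    wavelengths, or (n_wavelengths, ny, nx)), e.g. the output of
    :func:`wavekit.elements.zernike_phase_map` or
    :func:`wavekit.elements.seidel_phase_map`.

    The stack is normalized so the in-focus page (smallest |z|) sums to
    one, with the same factor applied to every page so relative defocus
    energy is preserved.
    """
    zs = [float(z) for z in np.atleast_1d(z_planes)]
    if not all(np.isfinite(zs)):
        raise ValueError("z planes must be finite")
    ab_pages = None
    if aberration is not None:
        ab = np.asarray(aberration, dtype=float)
        if ab.ndim == 2:
            ab_pages = [ab] * len(spectrum)
        elif ab.ndim == 3 and ab.shape[0] == len(spectrum):
            ab_pages = list(ab)
        else:
            raise ValueError("aberration map does not match the pupil raster")
        if ab.shape[-2:] != grid.shape:
            raise ValueError("aberration map does not match the pupil raster")

    pages = np.zeros((len(zs),) + grid.shape, dtype=float)
    for w, wl in enumerate(spectrum.wavelengths):
        ab = None if ab_pages is None else ab_pages[w]
        for i, z in enumerate(zs):
            a = coherent_psf_page(grid, na, wl, spectrum.n_medium, ab, z)
            pages[i] += spectrum.weights[w] * np.abs(a) ** 2
    focus = int(np.argmin(np.abs(zs)))
    total = pages[focus].sum()
    if total <= 0:
        raise ValueError("degenerate PSF: in-focus page has zero energy")
    return PSFStack(pages=pages / total, z_planes=tuple(zs), grid=grid)


# ---------------------------------------------------------------------------
# incoherent imaging


def incoherent_image_2d(sample: np.ndarray, psf: PSFStack) -> np.ndarray:
    """Snapshot image: Σ_z sample_z ⊛ psf_z, cropped to the sample shape."""
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 3:
        raise ValueError("sample must be (nz, ny, nx)")
    if sample.shape[0] != psf.nz:
        raise ValueError("sample plane count must equal PSF plane count")
    out = np.zeros(sample.shape[1:], dtype=float)
    for z in range(psf.nz):
        out += _conv_same(sample[z], psf.pages[z])
    return out


def incoherent_image_3d(sample: np.ndarray, psf: PSFStack,
                        sample_dz: float | None = None) -> np.ndarray:
    """Widefield volume image: full 3-D convolution with the 3-D PSF.

    When ``sample_dz`` is given it must match the PSF plane spacing.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 3:
        raise ValueError("sample must be (nz, ny, nx)")
    if sample_dz is not None and psf.nz > 1:
        if not np.isclose(sample_dz, psf.z_spacing(), rtol=1e-9):
            raise ValueError("PSF z-spacing must equal the sample z-spacing")
    return _conv_same(sample, psf.pages)
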