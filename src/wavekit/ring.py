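"""Rotationally-invariant spatially-varying imaging: ring convolution.

Many microscopes are rotationally symmetric, so their PSF varies only
with the radial distance of a point from the center of the field of
view, up to a rotation.  The imaging model is then: every sample pixel
p contributes its intensity times the PSF calibrated at radius |p|,
rotated to the azimuth of p.  :func:`sv_superposition_oracle` implements
this definition literally (a per-pixel superposition with bilinear
rotation) and serves as the reference; :func:`ring_convolve` computes
the same model efficiently by working in polar coordinates, where the
superposition becomes, for each radius, a circular convolution over the
azimuthal angle — evaluated with FFTs against rotationally
Fourier-transformed PSFs.

The efficient operator is linear in the sample and exposes its exact
adjoint, which gradient-based ring deconvolution uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates

from .field import SamplingGrid, Spectrum
from .elements import SeidelSpec, pupil_coords, seidel_phase_map
from .imaging import _conv_same, _conv_same_adjoint, coherent_psf_page

__all__ = [
    "RadialPSFSet",
    "radial_psf_line",
    "sv_superposition_oracle",
    "RingOperator",
    "ring_convolve",
]


@dataclass(frozen=True)
class RadialPSFSet:
    """Intensity PSF patches indexed by radial image-plane position.

    ``radii`` are in pixels from the FOV center, strictly increasing.
    """

    psfs: np.ndarray  # (n_radii, p, p)
    radii: tuple[float, ...]
    grid: SamplingGrid

    def __post_init__(self):
        psfs = np.asarray(self.psfs, dtype=float)
        radii = tuple(float(r) for r in np.atleast_1d(self.radii))
        if psfs.ndim != 3 or psfs.shape[0] != len(radii):
            raise ValueError("one PSF patch per radius required")
        if len(radii) == 0:
            raise ValueError("at least one radius required")
        if any(r < 0 for r in radii) or np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be nonnegative and strictly increasing")
        if np.any(psfs < -1e-12 * max(psfs.max(initial=0.0), 1.0)):
            raise ValueError("PSFs must be nonnegative")
        object.__setattr__(self, "psfs", psfs)
        object.__setattr__(self, "radii", radii)

    def nearest_index(self, r: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.radii) - r)))

    def spatially_invariant(self) -> bool:
        return all(np.array_equal(self.psfs[0], p) for p in self.psfs[1:])


def radial_psf_line(spec: SeidelSpec, grid: SamplingGrid, na: float,
                    wavelength: float, radii, fov_radius: float,
                    n_medium: float = 1.0) -> RadialPSFSet:
    """Simulate the PSF along one radial line from the FOV center.

    The field point for radius r (pixels) is ``(r / fov_radius, 0)`` —
    normalized coordinates have magnitude 1 at ``fov_radius`` pixels and
    scale beyond 1 outside the calibrated region.  Each patch is an
    in-focus 4f PSF with the Seidel pupil phase of that field point,
    centered on the patch raster and normalized to unit sum.
    """
    radii = [float(r) for r in np.atleast_1d(radii)]
    if len(radii) == 0:
        raise ValueError("at least one radius required")
    if fov_radius <= 0:
        raise ValueError("fov_radius must be positive")
    pages = []
    for r in radii:
        coords = pupil_coords(grid, na, wavelength,
                              field_point=(r / fov_radius, 0.0))
        phase = seidel_phase_map(coords, spec)
        a = coherent_psf_page(grid, na, wavelength, n_medium, phase, 0.0)
        p = np.abs(a) ** 2
        pages.append(p / p.sum())
    return RadialPSFSet(psfs=np.stack(pages), radii=tuple(radii), grid=grid)


# ---------------------------------------------------------------------------
# defining model: per-pixel superposition


def _rotate_patch(patch: np.ndarray, phi: float) -> np.ndarray:
    """Rotate about the patch center index (p // 2) by bilinear interpolation."""
    py, px = patch.shape
    cy, cx = py // 2, px // 2
    dy = np.arange(py)[:, None] - cy
    dx = np.arange(px)[None, :] - cx
    c, s = np.cos(phi), np.sin(phi)
    src_x = dx * c + dy * s
    src_y = -dx * s + dy * c
    # snap float noise so exact multiples of 90° stay exact at the borders
    for src in (src_x, src_y):
        near = np.abs(src - np.rint(src)) < 1e-9
        src[near] = np.rint(src[near])
    return map_coordinates(patch, [cy + src_y, cx + src_x], order=1, cval=0.0)


def _accumulate(canvas: np.ndarray, patch: np.ndarray, iy: int, ix: int,
                weight: float) -> None:
    ny, nx = canvas.shape
    py, px = patch.shape
    y0, x0 = iy - py // 2, ix - px // 2
    ys0, xs0 = max(0, -y0), max(0, -x0)
    yt0, xt0 = max(0, y0), max(0, x0)
    h = min(py - ys0, ny - yt0)
    w = min(px - xs0, nx - xt0)
    if h > 0 and w > 0:
        canvas[yt0:yt0 + h, xt0:xt0 + w] += weight * patch[ys0:ys0 + h, xs0:xs0 + w]


def sv_superposition_oracle(sample: np.ndarray, psfs: RadialPSFSet) -> np.ndarray:
    """Brute-force spatially-varying superposition (the defining model).

    For every pixel p with intensity s(p): add s(p) times the PSF at the
    radius nearest |p|, rotated to the azimuth of p, centered at p.
    Linear in the sample; quadratic cost — use for verification only.
    """
    sample = np.asarray(sample, dtype=float)
    ny, nx = sample.shape
    cy, cx = ny // 2, nx // 2
    out = np.zeros_like(sample)
    for iy, ix in zip(*np.nonzero(sample)):
        y, x = iy - cy, ix - cx
        r = float(np.hypot(y, x))
        phi = float(np.arctan2(y, x))
        patch = _rotate_patch(psfs.psfs[psfs.nearest_index(r)], phi)
        _accumulate(out, patch, iy, ix, sample[iy, ix])
    return out


# ---------------------------------------------------------------------------
# efficient path: azimuthal FFTs in polar coordinates


class RingOperator:
    """Linear operator computing the ring-convolution image model.

    The sample's mass is scattered bilinearly onto a polar raster
    (radius step one pixel, ``n_phi`` azimuthal samples); per input
    radius the contribution to every output radius is a circular
    convolution over azimuth, evaluated against precomputed azimuthal
    Fourier transforms of the radially-indexed PSFs; the polar result is
    gathered back bilinearly.  Cost per radius is ``O(n_phi log n_phi)``
    — linear rather than quadratic in the number of image rows.

    When every PSF in the set is identical the model is spatially
    invariant and the operator falls back to a single zero-padded FFT
    convolution, which is exact.
    """

    def __init__(self, psfs: RadialPSFSet, shape: tuple[int, int],
                 n_phi: int | None = None):
        self.psfs = psfs
        self.shape = tuple(shape)
        self._invariant = psfs.spatially_invariant()
        if self._invariant:
            return
        ny, nx = self.shape
        cy, cx = ny // 2, nx // 2
        corners = [(-cy, -cx), (-cy, nx - 1 - cx), (ny - 1 - cy, -cx),
                   (ny - 1 - cy, nx - 1 - cx)]
        rho_max = max(np.hypot(y, x) for y, x in corners)
        self.n_rho = int(np.ceil(rho_max)) + 2
        if n_phi is None:
            n_phi = 1 << int(np.ceil(np.log2(max(64, 8 * self.n_rho))))
        self.n_phi = int(n_phi)
        self._build_scatter()
        self._build_kernels()

    def _build_scatter(self) -> None:
        ny, nx = self.shape
        cy, cx = ny // 2, nx // 2
        yy, xx = np.meshgrid(np.arange(ny) - cy, np.arange(nx) - cx,
                             indexing="ij")
        rho = np.hypot(yy, xx).ravel()
        phi = np.mod(np.arctan2(yy, xx).ravel(), 2 * np.pi)
        d_phi = 2 * np.pi / self.n_phi

        k = np.clip(rho, 0, self.n_rho - 1 - 1e-9)
        k0 = np.floor(k).astype(int)
        fk = k - k0
        a = phi / d_phi
        a0 = np.floor(a).astype(int) % self.n_phi
        fa = a - np.floor(a)
        a1 = (a0 + 1) % self.n_phi

        npix = ny * nx
        cols = np.tile(np.arange(npix), 4)
        rows = np.concatenate([
            k0 * self.n_phi + a0,
            k0 * self.n_phi + a1,
            (k0 + 1) * self.n_phi + a0,
            (k0 + 1) * self.n_phi + a1,
        ])
        vals = np.concatenate([
            (1 - fk) * (1 - fa),
            (1 - fk) * fa,
            fk * (1 - fa),
            fk * fa,
        ])
        self._A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_rho * self.n_phi, npix))
        self._AT = self._A.T.tocsr()

    def _build_kernels(self) -> None:
        # Ghat[k_in, rho_out, m]: azimuthal FFT of the PSF nearest to input
        # radius k_in, evaluated on the polar output raster
        d_phi = 2 * np.pi / self.n_phi
        rho_out = np.arange(self.n_rho)[:, None]
        dphi = (np.arange(self.n_phi) * d_phi)[None, :]
        qx = rho_out * np.cos(dphi)
        qy = rho_out * np.sin(dphi)
        self._Ghat = np.empty((self.n_rho, self.n_rho, self.n_phi),
                              dtype=complex)
        cache: dict[int, np.ndarray] = {}
        for k in range(self.n_rho):
            j = self.psfs.nearest_index(float(k))
            if j not in cache:
                cache[j] = self.psfs.psfs[j]
            patch = cache[j]
            py, px = patch.shape
            G = map_coordinates(
                patch,
                [py // 2 + qy, px // 2 + (qx - float(k))],
                order=1, cval=0.0)
            self._Ghat[k] = np.fft.fft(G, axis=-1)

    def apply(self, sample: np.ndarray) -> np.ndarray:
        sample = np.asarray(sample, dtype=float)
        if sample.shape != self.shape:
            raise ValueError("sample shape does not match the operator")
        if self._invariant:
            return _conv_same(sample, self.psfs.psfs[0])
        s_pol = (self._A @ sample.ravel()).reshape(self.n_rho, self.n_phi)
        s_hat = np.fft.fft(s_pol, axis=1)
        out_hat = np.einsum("km,kom->om", s_hat, self._Ghat)
        out_pol = np.fft.ifft(out_hat, axis=1).real
        return (self._AT @ out_pol.ravel()).reshape(self.shape)

    def adjoint(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        if g.shape != self.shape:
            raise ValueError("cotangent shape does not match the operator")
        if self._invariant:
            k = self.psfs.psfs[0]
            return _conv_same_adjoint(g, k, self.shape, k.shape)
        g_pol = (self._A @ g.ravel()).reshape(self.n_rho, self.n_phi)
        g_hat = np.fft.fft(g_pol, axis=1)
        s_hat = np.einsum("kom,om->km", np.conj(self._Ghat), g_hat)
        s_pol = np.fft.ifft(s_hat, axis=1).real
        return (self._AT @ s_pol.ravel()).reshape(self.shape)


def ring_convolve(sample: np.ndarray, psfs: RadialPSFSet,
                  n_phi: int | None = None) -> np.ndarray:
    """Spatially-varying image via the efficient polar-FFT ring model."""
    sample = np.asarray(sample, dtype=float)
    return RingOperator(psfs, sample.shape, n_phi=n_phi).apply(sample)
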