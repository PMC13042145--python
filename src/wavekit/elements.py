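"""Pointwise optical elements and the lens-mediated Fourier transform.

Everything here is a multiplicative transform of the field except
:func:`ff_lens_to_focal_plane`, which is a scaled discrete Fourier
transform taking the field from the front focal plane of an ideal lens
to its back focal plane (pitch becomes ``λ f / (n N dx)``).

Aberrations come in two parameterizations used throughout computational
microscopy: Zernike polynomials in ANSI single-index ordering
(unnormalized), and the classical five-term Seidel expansion whose field
dependence is rotationally invariant — the pupil azimuth enters only
through the angle measured from the field-point direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .field import Field, SamplingGrid

__all__ = [
    "ZernikeSpec",
    "SeidelSpec",
    "PupilCoords",
    "apply_phase_mask",
    "thin_lens",
    "circular_pupil",
    "ansi_to_nm",
    "zernike_polynomial",
    "zernike_phase_map",
    "pupil_coords",
    "seidel_phase_map",
    "quantize_phase",
    "ff_lens_to_focal_plane",
    "ff_lens_inverse",
    "ff_lens_adjoint",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ZernikeSpec:
    """ANSI-indexed Zernike coefficients in waves (multiples of λ)."""

    indices: tuple[int, ...]
    coefficients: tuple[float, ...]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        co = tuple(float(c) for c in self.coefficients)
        if len(idx) != len(co):
            raise ValueError("indices and coefficients must have equal length")
        if any(i < 0 for i in idx):
            raise ValueError("ANSI indices must be nonnegative")
        if len(set(idx)) != len(idx):
            raise ValueError("ANSI indices must be unique")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "coefficients", co)


# coefficient order is pinned for config files:
# [sphere W040, coma W131, astigmatism W222, field curvature W220, distortion W311]
@dataclass(frozen=True)
class SeidelSpec:
    """Five Seidel coefficients in waves."""

    w: tuple[float, float, float, float, float]

    def __post_init__(self):
        w = tuple(float(v) for v in self.w)
        if len(w) != 5:
            raise ValueError("exactly five Seidel coefficients required")
        if not all(np.isfinite(w)):
            raise ValueError("Seidel coefficients must be finite")
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class PupilCoords:
    """Normalized pupil polar coordinates plus a normalized field point.

    ``rho`` is 1 at the pupil cutoff; ``(u, v)`` has magnitude ≤ 1 inside
    the calibrated field region and is allowed to exceed 1 outside it.
    """

    rho: np.ndarray
    theta: np.ndarray
    field_point: tuple[float, float] = (0.0, 0.0)


# ---------------------------------------------------------------------------
# multiplicative elements


def apply_phase_mask(field: Field, phase: np.ndarray) -> Field:
    """Multiply by ``exp(i·phase)``; modulus is preserved everywhere.

    ``phase`` is (ny, nx) shared across wavelengths or (n_wavelengths,
    ny, nx).
    """
    phase = np.asarray(phase, dtype=float)
    if phase.shape == field.shape:
        phase = np.broadcast_to(phase, field.u.shape)
    elif phase.shape != field.u.shape:
        raise ValueError(
            f"phase map shape {phase.shape} does not match field {field.u.shape}"
        )
    return field.with_u(field.u * np.exp(1j * phase))


def thin_lens(field: Field, f: float) -> Field:
    """Paraxial thin lens: ``exp(-i π n (x²+y²) / (λ f))`` per wavelength."""
    if f == 0:
        raise ValueError("focal length must be nonzero")
    n = field.spectrum.n_medium
    pages = np.empty_like(field.u)
    for w, wl in enumerate(field.spectrum.wavelengths):
        y, x = field.grid.coords(w)
        r2 = y[:, None] ** 2 + x[None, :] ** 2
        pages[w] = field.u[w] * np.exp(-1j * np.pi * n * r2 / (wl * f))
    return field.with_u(pages)


def circular_pupil(field: Field, cutoff: float, domain: str = "spatial") -> Field:
    """Hard circular aperture in the spatial or frequency domain.

    ``domain="spatial"``: ``cutoff`` is a diameter in µm; samples at radius
    beyond diameter/2 are zeroed.  ``domain="frequency"``: ``cutoff`` is a
    numerical aperture (medium index included, NA = n sin α); transverse
    frequencies beyond NA/λ (vacuum wavelength) are zeroed.  Both are
    projections, hence idempotent and power non-increasing.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pages = np.empty_like(field.u)
    if domain == "spatial":
        radius = cutoff / 2.0
        for w in range(field.n_wavelengths):
            y, x = field.grid.coords(w)
            mask = (y[:, None] ** 2 + x[None, :] ** 2) <= radius ** 2
            pages[w] = field.u[w] * mask
    elif domain == "frequency":
        for w, wl in enumerate(field.spectrum.wavelengths):
            dy, dx = field.grid.pitch(w)
            fy = np.fft.fftfreq(field.grid.ny, d=dy)[:, None]
            fx = np.fft.fftfreq(field.grid.nx, d=dx)[None, :]
            mask = (fy ** 2 + fx ** 2) <= (cutoff / wl) ** 2
            pages[w] = np.fft.ifft2(np.fft.fft2(field.u[w]) * mask)
    else:
        raise ValueError("domain must be 'spatial' or 'frequency'")
    return field.with_u(pages)


# ---------------------------------------------------------------------------
# Zernike aberrations (ANSI single-index, unnormalized)


def ansi_to_nm(j: int) -> tuple[int, int]:
    """ANSI single index → (radial order n, azimuthal frequency m)."""
    if j < 0:
        raise ValueError("ANSI index must be nonnegative")
    n = int(np.ceil((-3 + np.sqrt(9 + 8 * j)) / 2))
    m = 2 * j - n * (n + 2)
    return n, m


def _radial_poly(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m_abs) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k)
                * factorial((n + m_abs) // 2 - k)
                * factorial((n - m_abs) // 2 - k)))
        out += c * rho ** (n - 2 * k)
    return out


def zernike_polynomial(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Unnormalized Zernike polynomial Z_j on (ρ, θ); no disk masking."""
    n, m = ansi_to_nm(j)
    R = _radial_poly(n, abs(m), np.asarray(rho, dtype=float))
    if m > 0:
        return R * np.cos(m * np.asarray(theta))
    if m < 0:
        return R * np.sin(-m * np.asarray(theta))
    return R


def pupil_coords(grid: SamplingGrid, na: float, wavelength: float,
                 field_point: tuple[float, float] = (0.0, 0.0),
                 w: int = 0) -> PupilCoords:
    """Normalized pupil coordinates on the centered frequency raster.

    The pupil lives in the frequency plane of the image raster; ρ = 1 at
    transverse frequency NA/λ.  The map is *centered* (zero frequency at
    pixel ``N // 2``); shift with ``np.fft.ifftshift`` for use on the raw
    FFT raster.
    """
    if na <= 0:
        raise ValueError("numerical aperture must be positive")
    dy, dx = grid.pitch(w)
    fy = np.fft.fftshift(np.fft.fftfreq(grid.ny, d=dy))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(grid.nx, d=dx))[None, :]
    f_cut = na / wavelength
    rho = np.sqrt(fy ** 2 + fx ** 2) / f_cut
    theta = np.arctan2(np.broadcast_to(fy, rho.shape),
                       np.broadcast_to(fx, rho.shape))
    return PupilCoords(rho=rho, theta=theta, field_point=tuple(field_point))


def zernike_phase_map(grid: SamplingGrid, na: float, spec: ZernikeSpec,
                      wavelength: float) -> np.ndarray:
    """Pupil phase 2π Σ c_j Z_j(ρ, θ) in radians, zero outside ρ > 1.

    Returned on the centered frequency raster of ``grid`` (see
    :func:`pupil_coords`).  Linear in the coefficients.
    """
    coords = pupil_coords(grid, na, wavelength)
    inside = coords.rho <= 1.0
    phase = np.zeros(grid.shape, dtype=float)
    for j, c in zip(spec.indices, spec.coefficients):
        phase += 2 * np.pi * c * zernike_polynomial(j, coords.rho, coords.theta)
    return np.where(inside, phase, 0.0)


# ---------------------------------------------------------------------------
# Seidel aberrations


def seidel_phase_map(coords: PupilCoords, spec: SeidelSpec,
                     wavelength: float | None = None) -> np.ndarray:
    """Rotationally invariant Seidel wavefront, returned in radians.

    With h = |(u, v)| the normalized field height and θ' the pupil
    azimuth measured from the field-point direction,

        W(ρ, θ') = W040 ρ⁴ + W131 h ρ³ cosθ' + W222 h² ρ² cos²θ'
                 + W220 h² ρ² + W311 h³ ρ cosθ'      (waves)

    and the phase is 2π W.  Coefficients are already in waves, so the
    wavelength argument is accepted for interface symmetry but unused.
    """
    w040, w131, w222, w220, w311 = spec.w
    u, v = coords.field_point
    h = float(np.hypot(u, v))
    rho = coords.rho
    cos_t = np.cos(coords.theta - np.arctan2(v, u))
    W = (w040 * rho ** 4
         + w131 * h * rho ** 3 * cos_t
         + w222 * h ** 2 * rho ** 2 * cos_t ** 2
         + w220 * h ** 2 * rho ** 2
         + w311 * h ** 3 * rho * cos_t)
    return 2 * np.pi * W


# ---------------------------------------------------------------------------
# SLM quantization


def quantize_phase(phase: np.ndarray, bits: int) -> np.ndarray:
    """Wrap to [0, 2π) and round to 2**bits uniform levels; idempotent."""
    if not 1 <= int(bits) <= 16:
        raise ValueError("bits must be in [1, 16]")
    levels = 2 ** int(bits)
    step = 2 * np.pi / levels
    wrapped = np.mod(np.asarray(phase, dtype=float), 2 * np.pi)
    return (np.rint(wrapped / step) % levels) * step


# ---------------------------------------------------------------------------
# lens-mediated optical Fourier transform


def _centered_fft2(page: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(page)))


def _centered_ifft2(page: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(page)))


def _ff_scale(dy: float, dx: float, wl_m: float, f: float) -> complex:
    # amplitude chosen so power is conserved exactly (discrete Parseval)
    return dy * dx / (1j * wl_m * f)


def ff_lens_to_focal_plane(field: Field, f: float) -> Field:
    """Front-focal to back-focal plane map of an ideal lens.

    Each page becomes a scaled centered DFT; output pitch per wavelength
    and axis is ``λ f / (n N d)``.  The scaling ``d² / (i λ f)`` conserves
    total power exactly.
    """
    if f <= 0:
        raise ValueError("focal length must be positive")
    ny, nx = field.grid.shape
    n_med = field.spectrum.n_medium
    pages, dys, dxs = [], [], []
    for w, wl in enumerate(field.spectrum.wavelengths):
        wl_m = wl / n_med
        dy, dx = field.grid.pitch(w)
        scale = _ff_scale(dy, dx, wl_m, f)
        pages.append(scale * _centered_fft2(field.u[w]))
        dys.append(wl_m * f / (ny * dy))
        dxs.append(wl_m * f / (nx * dx))
    if len(pages) == 1:
        grid = SamplingGrid(ny, nx, dys[0], dxs[0])
    else:
        grid = SamplingGrid(ny, nx, tuple(dys), tuple(dxs))
    return field.with_u(np.stack(pages), grid=grid)


def ff_lens_inverse_page(page: np.ndarray, dy_in: float, dx_in: float,
                         wl_m: float, f: float) -> np.ndarray:
    """Exact inverse of the per-page focal-plane map (SLM-plane pitches)."""
    scale = _ff_scale(dy_in, dx_in, wl_m, f)
    return _centered_ifft2(page / scale)


def ff_lens_inverse(field: Field, f: float, grid_in: SamplingGrid) -> Field:
    """Invert :func:`ff_lens_to_focal_plane` back onto ``grid_in``."""
    if f <= 0:
        raise ValueError("focal length must be positive")
    n_med = field.spectrum.n_medium
    pages = []
    for w, wl in enumerate(field.spectrum.wavelengths):
        dy, dx = grid_in.pitch(w)
        pages.append(ff_lens_inverse_page(field.u[w], dy, dx, wl / n_med, f))
    return field.with_u(np.stack(pages), grid=grid_in)


def ff_lens_adjoint_page(g: np.ndarray, dy_in: float, dx_in: float,
                         wl_m: float, f: float) -> np.ndarray:
    """Adjoint (conjugate transpose) of the per-page focal-plane map."""
    scale = _ff_scale(dy_in, dx_in, wl_m, f)
    n_tot = g.shape[0] * g.shape[1]
    return np.conj(scale) * n_tot * _centered_ifft2(g)


def ff_lens_adjoint(field_grad: np.ndarray, grid_in: SamplingGrid,
                    wavelength: float, n_medium: float, f: float,
                    w: int = 0) -> np.ndarray:
    dy, dx = grid_in.pitch(w)
    return ff_lens_adjoint_page(field_grad, dy, dx, wavelength / n_medium, f)
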