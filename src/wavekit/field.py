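"""Structured scalar optical fields.

The :class:`Field` is the single state object every optical element
transforms: a stack of complex amplitude pages (one per wavelength) on a
shared pixel raster, together with the physical sampling, the source
spectrum and the current axial position.

Conventions (global to the library):

* all lengths are micrometres, all phases radians;
* pixel index ``i`` on an axis of length ``N`` sits at physical coordinate
  ``(i - N // 2) * pitch`` — the origin is the central sample, which makes
  on-axis symmetry exact for both even and odd rasters;
* intensity is in arbitrary units, power in those units times µm².
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SamplingGrid",
    "Spectrum",
    "Field",
    "center_coords",
    "create_plane_wave",
    "intensity_and_power",
]


def center_coords(n: int, pitch: float) -> np.ndarray:
    """Physical coordinates of the samples on one axis, origin at ``n // 2``."""
    return (np.arange(n) - n // 2) * pitch


def _as_pitch_tuple(p) -> tuple[float, ...] | float:
    if np.isscalar(p):
        return float(p)
    return tuple(float(v) for v in p)


@dataclass(frozen=True)
class SamplingGrid:
    """Pixel counts and physical pixel pitch.

    ``dy``/``dx`` are either scalars shared by every wavelength or one
    value per wavelength (needed after lens Fourier transforms, whose
    output pitch is wavelength dependent).
    """

    ny: int
    nx: int
    dy: float | tuple[float, ...]
    dx: float | tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "dy", _as_pitch_tuple(self.dy))
        object.__setattr__(self, "dx", _as_pitch_tuple(self.dx))
        if int(self.ny) < 2 or int(self.nx) < 2:
            raise ValueError("grid must have at least 2 samples per axis")
        object.__setattr__(self, "ny", int(self.ny))
        object.__setattr__(self, "nx", int(self.nx))
        for p in (self.dy, self.dx):
            vals = (p,) if np.isscalar(p) else p
            if any(v <= 0 for v in vals):
                raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def per_wavelength(self) -> bool:
        return not (np.isscalar(self.dy) and np.isscalar(self.dx))

    def n_pitches(self) -> int:
        """Number of distinct pitch entries (1 when shared)."""
        n = 1
        for p in (self.dy, self.dx):
            if not np.isscalar(p):
                n = max(n, len(p))
        return n

    def pitch(self, w: int = 0) -> tuple[float, float]:
        """(dy, dx) for wavelength index ``w``."""
        dy = self.dy if np.isscalar(self.dy) else self.dy[w]
        dx = self.dx if np.isscalar(self.dx) else self.dx[w]
        return float(dy), float(dx)

    def coords(self, w: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinate vectors for wavelength index ``w``."""
        dy, dx = self.pitch(w)
        return center_coords(self.ny, dy), center_coords(self.nx, dx)

    def validate_for(self, n_wavelengths: int) -> None:
        for p in (self.dy, self.dx):
            if not np.isscalar(p) and len(p) != n_wavelengths:
                raise ValueError(
                    f"per-wavelength pitch count {len(p)} does not match "
                    f"{n_wavelengths} wavelengths"
                )


@dataclass(frozen=True)
class Spectrum:
    """Vacuum wavelengths (µm), relative spectral weights and medium index.

    Weights are normalised to sum to one on construction.
    """

    wavelengths: tuple[float, ...]
    weights: tuple[float, ...] | None = None
    n_medium: float = 1.0

    def __post_init__(self):
        wl = tuple(float(w) for w in np.atleast_1d(self.wavelengths))
        if any(w <= 0 for w in wl):
            raise ValueError("wavelengths must be strictly positive")
        if self.n_medium <= 0:
            raise ValueError("n_medium must be positive")
        if self.weights is None:
            wt = np.full(len(wl), 1.0 / len(wl))
        else:
            wt = np.asarray(self.weights, dtype=float)
            if wt.shape != (len(wl),):
                raise ValueError("one weight per wavelength required")
            if np.any(wt < 0) or wt.sum() <= 0:
                raise ValueError("weights must be nonnegative with positive sum")
            wt = wt / wt.sum()
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "weights", tuple(float(v) for v in wt))
        object.__setattr__(self, "n_medium", float(self.n_medium))

    def __len__(self) -> int:
        return len(self.wavelengths)

    def wavelength_in_medium(self, w: int = 0) -> float:
        return self.wavelengths[w] / self.n_medium

    @classmethod
    def monochromatic(cls, wavelength: float, n_medium: float = 1.0) -> "Spectrum":
        return cls(wavelengths=(wavelength,), n_medium=n_medium)


@dataclass(frozen=True)
class Field:
    """Complex scalar field: one (ny, nx) page per wavelength at axial z."""

    u: np.ndarray  # complex, shape (n_wavelengths, ny, nx)
    grid: SamplingGrid
    spectrum: Spectrum
    z: float = 0.0

    def __post_init__(self):
        u = np.asarray(self.u)
        if u.ndim == 2:
            u = u[None]
        u = np.ascontiguousarray(u, dtype=np.complex128)
        if u.ndim != 3:
            raise ValueError("field samples must be (n_wavelengths, ny, nx)")
        if u.shape[0] != len(self.spectrum):
            raise ValueError("page count must equal wavelength count")
        if u.shape[1:] != self.grid.shape:
            raise ValueError("pages must match the grid shape")
        if not np.all(np.isfinite(u)):
            raise ValueError("field samples must be finite")
        self.grid.validate_for(len(self.spectrum))
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "z", float(self.z))

    @property
    def n_wavelengths(self) -> int:
        return len(self.spectrum)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def with_u(self, u: np.ndarray, *, grid: SamplingGrid | None = None,
               z: float | None = None) -> "Field":
        return replace(self, u=u, grid=grid if grid is not None else self.grid,
                       z=self.z if z is None else z)

    def intensity(self) -> np.ndarray:
        """Spectral-weighted intensity image, arbitrary units."""
        w = np.asarray(self.spectrum.weights)[:, None, None]
        return np.sum(w * np.abs(self.u) ** 2, axis=0)

    def power(self) -> float:
        """Total power = Σ intensity · pixel area, per-wavelength pitches honoured."""
        total = 0.0
        for i, wt in enumerate(self.spectrum.weights):
            dy, dx = self.grid.pitch(i)
            total += wt * float(np.sum(np.abs(self.u[i]) ** 2)) * dy * dx
        return total


def create_plane_wave(
    grid: SamplingGrid,
    spectrum: Spectrum,
    amplitude: float = 1.0,
    tilt: Sequence[float] | None = None,
) -> Field:
    """Uniform-amplitude plane wave, optionally tilted.

    ``tilt = (theta_y, theta_x)`` in radians gives each page the carrier
    ``exp(i 2π n/λ (sinθx · x + sinθy · y))``.  Tilts whose transverse
    spatial frequency exceeds the raster Nyquist limit are rejected
    (aliased carrier).
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    ty, tx = (0.0, 0.0) if tilt is None else (float(tilt[0]), float(tilt[1]))
    if abs(ty) >= np.pi / 2 or abs(tx) >= np.pi / 2:
        raise ValueError("tilt angles must satisfy |theta| < pi/2")
    grid.validate_for(len(spectrum))

    n = spectrum.n_medium
    pages = np.empty((len(spectrum), grid.ny, grid.nx), dtype=np.complex128)
    for w, wl in enumerate(spectrum.wavelengths):
        dy, dx = grid.pitch(w)
        fy = n * np.sin(ty) / wl
        fx = n * np.sin(tx) / wl
        if abs(fy) > 1.0 / (2 * dy) + 1e-15 or abs(fx) > 1.0 / (2 * dx) + 1e-15:
            raise ValueError(
                f"tilt carrier frequency ({fy:.4g}, {fx:.4g}) /µm exceeds the "
                f"Nyquist limit of the raster"
            )
        y, x = grid.coords(w)
        phase = 2 * np.pi * (fy * y[:, None] + fx * x[None, :])
        pages[w] = amplitude * np.exp(1j * phase)
    return Field(u=pages, grid=grid, spectrum=spectrum, z=0.0)


def intensity_and_power(field: Field) -> tuple[np.ndarray, float]:
    """Weighted intensity image and its integral over the raster."""
    return field.intensity(), field.power()
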