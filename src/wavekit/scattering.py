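"""Multislice beam propagation through a refractive-index-contrast volume.

A thick transparent sample is modeled as a stack of thin phase screens
separated by short free-space diffraction steps: at slice j the field
picks up ``exp(i 2π Δn_j dz / λ)`` (vacuum wavenumber times the index
contrast) and then diffracts over dz in the background medium via the
angular spectrum method.  The screen is applied at the slice entrance;
slice-refinement consistency makes this ordering convention benign.

A complex Δn is accepted — its imaginary part attenuates the amplitude —
in which case the steps are no longer unitary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import Field, SamplingGrid
from .propagation import PropagationSettings, apply_transfer_page, asm_kernel

__all__ = [
    "RefractiveIndexVolume",
    "multislice_propagate",
    "multislice_intensity_stack",
]


@dataclass(frozen=True)
class RefractiveIndexVolume:
    """Voxel grid of index contrast Δn over an (nz, ny, nx) raster."""

    dn: np.ndarray
    dz: float
    grid: SamplingGrid
    n_background: float = 1.0

    def __post_init__(self):
        dn = np.asarray(self.dn)
        if dn.ndim != 3:
            raise ValueError("dn must be (nz, ny, nx)")
        if dn.shape[1:] != self.grid.shape:
            raise ValueError("transverse shape must match the grid")
        if self.dz <= 0:
            raise ValueError("slice thickness must be positive")
        if self.n_background <= 0:
            raise ValueError("background index must be positive")
        object.__setattr__(self, "dn", dn)
        object.__setattr__(self, "dz", float(self.dz))
        object.__setattr__(self, "n_background", float(self.n_background))

    @property
    def nz(self) -> int:
        return self.dn.shape[0]

    @property
    def thickness(self) -> float:
        return self.nz * self.dz


def _check_grids(field: Field, volume: RefractiveIndexVolume) -> None:
    if field.grid.shape != volume.grid.shape:
        raise ValueError("field and volume grids must have equal shape")
    for w in range(field.n_wavelengths):
        if field.grid.pitch(w) != volume.grid.pitch(0 if not volume.grid.per_wavelength else w):
            raise ValueError("field and volume pixel pitches must match")


def _step_kernels(field: Field, volume: RefractiveIndexVolume,
                  settings: PropagationSettings) -> list[np.ndarray]:
    kernels = []
    shape = (field.grid.ny * settings.pad_factor,
             field.grid.nx * settings.pad_factor)
    for w, wl in enumerate(field.spectrum.wavelengths):
        dy, dx = field.grid.pitch(w)
        kernels.append(asm_kernel(shape, dy, dx, wl, volume.n_background,
                                  volume.dz, band_limit=settings.band_limit,
                                  keep_evanescent=settings.keep_evanescent))
    return kernels


def multislice_propagate(field: Field, volume: RefractiveIndexVolume,
                         settings: PropagationSettings = PropagationSettings(),
                         ) -> Field:
    """Propagate through the whole volume; output z advances by nz·dz."""
    _check_grids(field, volume)
    kernels = _step_kernels(field, volume, settings)
    pages = field.u.copy()
    for j in range(volume.nz):
        for w, wl in enumerate(field.spectrum.wavelengths):
            screen = np.exp(1j * (2 * np.pi / wl) * volume.dn[j] * volume.dz)
            pages[w] = apply_transfer_page(pages[w] * screen, kernels[w],
                                           settings.pad_factor)
    return field.with_u(pages, z=field.z + volume.thickness)


def multislice_intensity_stack(field: Field, volume: RefractiveIndexVolume,
                               settings: PropagationSettings = PropagationSettings(),
                               ) -> np.ndarray:
    """Intensity after each phase-screen + diffraction step, shape (nz, ny, nx).

    The final plane is the intensity of :func:`multislice_propagate`'s
    output field.
    """
    _check_grids(field, volume)
    kernels = _step_kernels(field, volume, settings)
    pages = field.u.copy()
    weights = np.asarray(field.spectrum.weights)
    stack = np.empty((volume.nz,) + field.grid.shape, dtype=float)
    for j in range(volume.nz):
        for w, wl in enumerate(field.spectrum.wavelengths):
            screen = np.exp(1j * (2 * np.pi / wl) * volume.dn[j] * volume.dz)
            pages[w] = apply_transfer_page(pages[w] * screen, kernels[w],
                                           settings.pad_factor)
        stack[j] = np.sum(weights[:, None, None] * np.abs(pages) ** 2, axis=0)
    return stack
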