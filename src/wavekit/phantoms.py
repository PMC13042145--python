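"""Seeded synthetic phantoms: point sources, dot targets, spheres, beads.

Every generator is a pure function of its :class:`PhantomConfig` — the
seed is mandatory, all randomness flows through one generator per call,
and identical configs produce identical arrays.  These phantoms stand
in for experimental datasets so the whole library builds and tests
without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .field import SamplingGrid
from .scattering import RefractiveIndexVolume

__all__ = [
    "PhantomConfig",
    "MULTICOLOR_WAVELENGTHS",
    "gen_point_sources",
    "gen_dot_target_planes",
    "gen_ri_sphere_phantom",
    "gen_bead_volume",
]

# 25 emission wavelengths spanning 400-650 nm (µm)
MULTICOLOR_WAVELENGTHS: tuple[float, ...] = tuple(
    np.round(np.linspace(0.400, 0.650, 25), 6))


@dataclass(frozen=True)
class PhantomConfig:
    """Shape, physical pitch, mandatory seed and object parameters."""

    shape: tuple[int, ...]
    pitch: tuple[float, ...] = (1.0, 1.0)
    seed: int = 0
    n_objects: int = 10
    radius: float = 3.0          # voxels, for spheres/beads
    dn: float = 0.02             # index contrast for RI phantoms
    intensity_range: tuple[float, float] = (0.25, 1.0)
    margin: int = 4              # inset from the array edges
    n_background: float = 1.0
    dz: float = 1.0              # slice thickness (µm) for RI volumes

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if any(s <= 0 for s in shape):
            raise ValueError("shape entries must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for phantom generation")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "pitch", tuple(float(p) for p in self.pitch))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_positions(rng, shape, margin, n):
    # clamp the inset per axis so thin volumes still admit placements
    lo = [min(margin, (s - 1) // 2) for s in shape]
    hi = [s - m for s, m in zip(shape, lo)]
    if any(h <= l for l, h in zip(lo, hi)):
        raise ValueError("margin leaves no room for objects")
    return np.stack([rng.integers(l, h, size=n) for l, h in zip(lo, hi)],
                    axis=1)


def gen_point_sources(config: PhantomConfig, multicolor: bool = False):
    """Seeded point emitters on a dark background (2-D or 3-D).

    With ``multicolor=True`` every point additionally gets an emission
    wavelength drawn from the 25-value grid 0.400–0.650 µm (10 nm
    steps); returns ``(array, wavelengths)``, otherwise ``(array, None)``.
    """
    if config.n_objects < 1:
        raise ValueError("at least one point source required")
    if config.n_objects > int(np.prod(config.shape)):
        raise ValueError("more points than pixels requested")
    rng = config.rng()
    pos = _random_positions(rng, config.shape, config.margin, config.n_objects)
    lo, hi = config.intensity_range
    out = np.zeros(config.shape)
    out[tuple(pos.T)] = rng.uniform(lo, hi, size=config.n_objects)
    if not multicolor:
        return out, None
    wl = rng.choice(MULTICOLOR_WAVELENGTHS, size=config.n_objects)
    return out, wl


def gen_dot_target_planes(config: PhantomConfig, n_planes: int = 3):
    """Holography target: planes of dots with varying intensities in (0, 1]."""
    if n_planes < 1:
        raise ValueError("at least one plane required")
    rng = config.rng()
    if len(config.shape) != 2:
        raise ValueError("dot targets are per-plane 2-D images")
    planes = []
    for _ in range(n_planes):
        pos = _random_positions(rng, config.shape, config.margin,
                                config.n_objects)
        img = np.zeros(config.shape)
        img[tuple(pos.T)] = rng.uniform(np.nextafter(0, 1), 1.0,
                                        size=config.n_objects)
        planes.append(img)
    return planes


def _sphere_mask(shape, center, radius):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def gen_ri_sphere_phantom(config: PhantomConfig) -> RefractiveIndexVolume:
    """Refractive-index contrast spheres in an empty background volume.

    Overlapping spheres take the maximum contrast.  ``config.pitch``
    supplies (dy, dx); ``config.dz`` the slice thickness.
    """
    if len(config.shape) != 3:
        raise ValueError("RI phantoms are 3-D")
    nz, ny, nx = config.shape
    if config.n_objects > 0 and any(
            2 * config.radius >= s for s in config.shape):
        raise ValueError("sphere radius does not fit in the volume")
    rng = config.rng()
    dn = np.zeros(config.shape)
    if config.n_objects > 0:
        margin = max(config.margin, int(np.ceil(config.radius)))
        pos = _random_positions(rng, config.shape, margin, config.n_objects)
        for c in pos:
            mask = _sphere_mask(config.shape, c, config.radius)
            dn[mask] = np.maximum(dn[mask], config.dn)
    grid = SamplingGrid(ny, nx, config.pitch[-2], config.pitch[-1])
    return RefractiveIndexVolume(dn=dn, dz=config.dz, grid=grid,
                                 n_background=config.n_background)


def gen_bead_volume(config: PhantomConfig) -> np.ndarray:
    """Fluorescent-bead-like intensity volume: solid spherical blobs."""
    if len(config.shape) != 3:
        raise ValueError("bead volumes are 3-D")
    rng = config.rng()
    margin = max(config.margin, int(np.ceil(config.radius)))
    pos = _random_positions(rng, config.shape, margin, config.n_objects)
    lo, hi = config.intensity_range
    levels = rng.uniform(lo, hi, size=config.n_objects)
    out = np.zeros(config.shape)
    for c, level in zip(pos, levels):
        mask = _sphere_mask(config.shape, c, config.radius)
        out[mask] = np.maximum(out[mask], level)
    return out
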