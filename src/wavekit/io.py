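"""TIFF + JSON-sidecar serialization for all stack-shaped objects.

Multi-page 32-bit float TIFF is the interchange format for every image,
PSF and volume; physical metadata that baseline TIFF tags cannot carry
(pitch, slice thickness, wavelengths, axial positions) lives in a JSON
sidecar next to the stack (same path, ``.json`` suffix).  Complex
fields serialize as a pair of stacks (real and imaginary parts) sharing
one sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .field import Field, SamplingGrid, Spectrum
from .imaging import PSFStack
from .ring import RadialPSFSet
from .scattering import RefractiveIndexVolume

__all__ = [
    "SidecarError",
    "write_stack",
    "read_stack",
    "save_field",
    "load_field",
    "save_volume",
    "load_volume",
    "save_psf_stack",
    "load_psf_stack",
    "save_radial_psfs",
    "load_radial_psfs",
]


class SidecarError(ValueError):
    """Malformed or missing JSON sidecar (distinct from a missing stack)."""


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(path, stack: np.ndarray, sidecar: dict | None = None) -> None:
    """Write a 2-D/3-D float array as multi-page float32 TIFF (+ sidecar)."""
    stack = np.asarray(stack)
    if stack.ndim not in (2, 3):
        raise ValueError("stack must be 2-D or 3-D")
    if not np.all(np.isfinite(stack)):
        raise ValueError("stack values must be finite")
    tifffile.imwrite(Path(path), stack.astype(np.float32),
                     photometric="minisblack")
    if sidecar is not None:
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_stack(path, require_sidecar: bool = False):
    """Read a stack and its sidecar; returns ``(array, metadata_dict)``."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such stack: {p}")
    arr = tifffile.imread(p)
    sc = _sidecar_path(path)
    meta: dict = {}
    if sc.exists():
        try:
            meta = json.loads(sc.read_text())
        except json.JSONDecodeError as e:
            raise SidecarError(f"malformed sidecar {sc}: {e}") from e
        if not isinstance(meta, dict):
            raise SidecarError(f"sidecar {sc} must hold a JSON object")
    elif require_sidecar:
        raise SidecarError(f"missing sidecar {sc}")
    return np.asarray(arr), meta


# ---------------------------------------------------------------------------
# typed objects


def _grid_meta(grid: SamplingGrid) -> dict:
    return {"ny": grid.ny, "nx": grid.nx, "dy": grid.dy, "dx": grid.dx}


def _grid_from_meta(m: dict) -> SamplingGrid:
    def p(v):
        return tuple(v) if isinstance(v, list) else v
    return SamplingGrid(m["ny"], m["nx"], p(m["dy"]), p(m["dx"]))


def save_field(path_prefix, field: Field) -> None:
    """Serialize a complex field as <prefix>.real.tif / .imag.tif / .json."""
    prefix = Path(path_prefix)
    tifffile.imwrite(prefix.with_suffix(".real.tif"),
                     field.u.real.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(prefix.with_suffix(".imag.tif"),
                     field.u.imag.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "grid": _grid_meta(field.grid),
        "spectrum": {
            "wavelengths": list(field.spectrum.wavelengths),
            "weights": list(field.spectrum.weights),
            "n_medium": field.spectrum.n_medium,
        },
        "z": field.z,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_field(path_prefix) -> Field:
    prefix = Path(path_prefix)
    re_p = prefix.with_suffix(".real.tif")
    im_p = prefix.with_suffix(".imag.tif")
    sc = prefix.with_suffix(".json")
    if not re_p.exists() or not im_p.exists():
        raise FileNotFoundError(f"missing field stacks for prefix {prefix}")
    if not sc.exists():
        raise SidecarError(f"missing field sidecar {sc}")
    try:
        meta = json.loads(sc.read_text())
        spectrum = Spectrum(
            wavelengths=tuple(meta["spectrum"]["wavelengths"]),
            weights=tuple(meta["spectrum"]["weights"]),
            n_medium=meta["spectrum"]["n_medium"],
        )
        grid = _grid_from_meta(meta["grid"])
        z = float(meta["z"])
    except (KeyError, TypeError, json.JSONDecodeError) as e:
        raise SidecarError(f"malformed field sidecar {sc}: {e}") from e
    re = tifffile.imread(re_p)
    im = tifffile.imread(im_p)
    u = np.asarray(re, dtype=float) + 1j * np.asarray(im, dtype=float)
    if u.ndim == 2:
        u = u[None]
    return Field(u=u, grid=grid, spectrum=spectrum, z=z)


def save_volume(path, volume: RefractiveIndexVolume) -> None:
    dy, dx = volume.grid.pitch(0)
    write_stack(path, volume.dn.real, {
        "kind": "refractive_index_volume",
        "dz": volume.dz, "dy": dy, "dx": dx,
        "n_background": volume.n_background,
    })


def load_volume(path) -> RefractiveIndexVolume:
    arr, meta = read_stack(path, require_sidecar=True)
    try:
        grid = SamplingGrid(arr.shape[-2], arr.shape[-1],
                            meta["dy"], meta["dx"])
        return RefractiveIndexVolume(
            dn=arr if arr.ndim == 3 else arr[None],
            dz=meta["dz"], grid=grid,
            n_background=meta.get("n_background", 1.0))
    except (KeyError, TypeError) as e:
        raise SidecarError(f"malformed volume sidecar for {path}: {e}") from e


def save_psf_stack(path, psf: PSFStack) -> None:
    dy, dx = psf.grid.pitch(0)
    write_stack(path, psf.pages, {
        "kind": "psf_stack", "z_planes": list(psf.z_planes),
        "dy": dy, "dx": dx,
    })


def load_psf_stack(path) -> PSFStack:
    arr, meta = read_stack(path, require_sidecar=True)
    if arr.ndim == 2:
        arr = arr[None]
    try:
        grid = SamplingGrid(arr.shape[-2], arr.shape[-1],
                            meta["dy"], meta["dx"])
        return PSFStack(pages=arr, z_planes=tuple(meta["z_planes"]), grid=grid)
    except (KeyError, TypeError) as e:
        raise SidecarError(f"malformed PSF sidecar for {path}: {e}") from e


def save_radial_psfs(path, psfs: RadialPSFSet) -> None:
    dy, dx = psfs.grid.pitch(0)
    write_stack(path, psfs.psfs, {
        "kind": "radial_psf_set", "radii": list(psfs.radii),
        "dy": dy, "dx": dx,
    })


def load_radial_psfs(path) -> RadialPSFSet:
    arr, meta = read_stack(path, require_sidecar=True)
    if arr.ndim == 2:
        arr = arr[None]
    try:
        grid = SamplingGrid(arr.shape[-2], arr.shape[-1],
                            meta["dy"], meta["dx"])
        return RadialPSFSet(psfs=arr, radii=tuple(meta["radii"]), grid=grid)
    except (KeyError, TypeError) as e:
        raise SidecarError(f"malformed radial-PSF sidecar for {path}: {e}") from e
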