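"""Gradient-based inverse-problem drivers built on the forward models.

Five drivers cover the library's inverse-problem surface:

* :func:`gerchberg_saxton` — classic alternating-projection phase
  retrieval for Fourier holography;
* :func:`optimize_cgh_phase` — gradient-based computer-generated
  holography for multi-plane targets, through free space or through a
  scattering volume (multislice);
* :func:`estimate_zernike_coefficients` — recover pupil Zernike
  coefficients of an aberrated widefield microscope from a measured
  volume of a known sample;
* :func:`reconstruct_refractive_index` — multi-angle intensity
  diffraction tomography: per-angle gradient steps on image MSE, a total
  variation proximal smoothing after each epoch, and Nesterov momentum
  between the smoothed iterates;
* :func:`ring_deconvolve` — spatially-varying deconvolution under the
  ring-convolution model with a nonnegativity projection.

All gradients are hand-written adjoints in Wirtinger calculus.  For a
real loss L of a complex field u the backpropagated quantity is
``g = ∂L/∂u*``; through a complex-linear operator A it pulls back as
``A^H g``, and a phase parameter θ in ``u·exp(iθ)`` receives
``dL/dθ = 2 Im(conj(u_out) g)``.  Every adjoint is validated against
central finite differences (:func:`wavekit.optim.gradcheck_fd`).
"""

from __future__ import annotations

import numpy as np

from .field import SamplingGrid, Spectrum, create_plane_wave
from .propagation import PropagationSettings, apply_transfer_page, asm_kernel
from .elements import (
    ff_lens_adjoint_page,
    ff_lens_inverse_page,
    quantize_phase,
    zernike_polynomial,
    pupil_coords,
    _centered_fft2,
    _ff_scale,
)
from .scattering import RefractiveIndexVolume
from .imaging import (
    _conv_same,
    _conv_same_adjoint,
    _centered_ifft2,
    defocus_phase,
    pupil_disk,
)
from .ring import RadialPSFSet, RingOperator
from .losses import get_loss
from .optim import GradientReport, OptimizerConfig, gradcheck_fd, run_gradient_descent

__all__ = [
    "gerchberg_saxton",
    "simulate_cgh_planes",
    "optimize_cgh_phase",
    "estimate_zernike_coefficients",
    "tv_prox",
    "reconstruct_refractive_index",
    "ring_deconvolve",
    "gradcheck_element_chain",
    "gradcheck_multislice",
]


def _single_wavelength(spectrum: Spectrum) -> float:
    if len(spectrum) != 1:
        raise ValueError("this driver operates on a monochromatic field")
    return spectrum.wavelengths[0]


def _cifft2_adjoint(g: np.ndarray) -> np.ndarray:
    return _centered_fft2(g) / g.size


# ---------------------------------------------------------------------------
# Gerchberg-Saxton


def gerchberg_saxton(target_amplitude: np.ndarray, grid: SamplingGrid,
                     spectrum: Spectrum, f: float, iters: int,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Alternating-projection phase retrieval for a Fourier hologram.

    Alternates between the unit-amplitude constraint at the SLM plane
    and the target-amplitude constraint at the focal plane of the
    Fourier-transforming lens.  Returns the SLM phase in [0, 2π) and the
    relative focal-plane amplitude-error trace, which is non-increasing.
    """
    t = np.asarray(target_amplitude, dtype=float)
    if t.shape != grid.shape:
        raise ValueError("target shape must match the grid")
    if np.all(t == 0):
        raise ValueError("target amplitude must not be identically zero")
    if iters < 1:
        raise ValueError("at least one iteration required")
    wl_m = _single_wavelength(spectrum) / spectrum.n_medium
    dy, dx = grid.pitch(0)
    scale = _ff_scale(dy, dx, wl_m, f)

    # rescale the target so its total power matches a unit-amplitude SLM
    # field put through the (power-conserving) lens transform
    ny, nx = grid.shape
    dy2 = wl_m * f / (ny * dy)
    dx2 = wl_m * f / (nx * dx)
    p_slm = ny * nx * dy * dx
    p_t = float(np.sum(t ** 2)) * dy2 * dx2
    t = t * np.sqrt(p_slm / p_t)

    rng = np.random.default_rng(seed)
    phi = rng.uniform(0, 2 * np.pi, size=grid.shape)
    errors = np.empty(iters)
    t_norm = np.linalg.norm(t)
    for it in range(iters):
        v = scale * _centered_fft2(np.exp(1j * phi))
        errors[it] = np.linalg.norm(np.abs(v) - t) / t_norm
        v_proj = t * np.exp(1j * np.angle(v))
        u = ff_lens_inverse_page(v_proj, dy, dx, wl_m, f)
        phi = np.mod(np.angle(u), 2 * np.pi)
    return phi, errors


# ---------------------------------------------------------------------------
# multislice forward/backward shared by CGH-through-scattering and tomography


def _ms_kernel(grid: SamplingGrid, wl: float, n_background: float, dz: float,
               settings: PropagationSettings) -> np.ndarray:
    dy, dx = grid.pitch(0)
    shape = (grid.ny * settings.pad_factor, grid.nx * settings.pad_factor)
    return asm_kernel(shape, dy, dx, wl, n_background, dz,
                      band_limit=settings.band_limit,
                      keep_evanescent=settings.keep_evanescent)


def _ms_forward(page: np.ndarray, dn: np.ndarray, dz: float, wl: float,
                H: np.ndarray, pad: int):
    """One multislice pass keeping every intermediate field (for backprop).

    Returns (fields after each phase screen, fields after each full step).
    """
    after_screen, after_step = [], []
    u = page
    k0dz = 2 * np.pi * dz / wl
    for j in range(dn.shape[0]):
        v = u * np.exp(1j * k0dz * dn[j])
        after_screen.append(v)
        u = apply_transfer_page(v, H, pad)
        after_step.append(u)
    return after_screen, after_step


def _ms_backward_dn(after_screen, dn: np.ndarray, dz: float, wl: float,
                    H: np.ndarray, pad: int, g_final: np.ndarray,
                    injections=None) -> np.ndarray:
    """Backpropagate ∂L/∂u* through the slices; return dL/dΔn (real Δn).

    ``g_final`` is the cotangent on the output field; ``injections[j]``
    (optional) is an extra cotangent on the field after step j, used
    when the loss also touches intermediate intensity planes.
    """
    nz = dn.shape[0]
    ddn = np.empty(dn.shape)
    k0dz = 2 * np.pi * dz / wl
    g = g_final
    for j in range(nz - 1, -1, -1):
        if injections is not None and injections[j] is not None:
            g = g + injections[j]
        g_v = apply_transfer_page(g, H, pad, conjugate_kernel=True)
        v = after_screen[j]
        ddn[j] = 2.0 * np.imag(np.conj(v) * g_v) * k0dz
        g = g_v * np.exp(-1j * k0dz * dn[j])
    return ddn


# ---------------------------------------------------------------------------
# computer-generated holography


def simulate_cgh_planes(phase: np.ndarray, grid: SamplingGrid,
                        spectrum: Spectrum, f: float, z_planes,
                        scatter: RefractiveIndexVolume | None = None,
                        settings: PropagationSettings = PropagationSettings(),
                        quantize_bits: int | None = None) -> list[np.ndarray]:
    """Intensities produced by an SLM phase in the Fourier-holography model.

    Plane wave → phase mask (optionally quantized) → Fourier-transforming
    lens → per-plane angular-spectrum propagation (free space), or — when
    ``scatter`` is given — multislice propagation through the volume,
    with each requested z matched to the nearest slice plane.
    """
    wl = _single_wavelength(spectrum)
    wl_m = wl / spectrum.n_medium
    dy, dx = grid.pitch(0)
    if quantize_bits is not None:
        phase = quantize_phase(phase, quantize_bits)
    u1 = np.exp(1j * np.asarray(phase, dtype=float))
    u2 = _ff_scale(dy, dx, wl_m, f) * _centered_fft2(u1)
    ny, nx = grid.shape
    focal_grid = SamplingGrid(ny, nx, wl_m * f / (ny * dy), wl_m * f / (nx * dx))
    if scatter is None:
        out = []
        for z in np.atleast_1d(z_planes):
            H = _ms_kernel(focal_grid, wl, spectrum.n_medium, float(z), settings)
            u3 = apply_transfer_page(u2, H, settings.pad_factor)
            out.append(np.abs(u3) ** 2)
        return out
    H = _ms_kernel(focal_grid, wl, scatter.n_background, scatter.dz, settings)
    _, after_step = _ms_forward(u2, scatter.dn, scatter.dz, wl, H,
                                settings.pad_factor)
    out = []
    for z in np.atleast_1d(z_planes):
        j = int(np.argmin(np.abs((np.arange(scatter.nz) + 1) * scatter.dz - z)))
        out.append(np.abs(after_step[j]) ** 2)
    return out


def _cgh_value_and_grad(phase, targets, grid, spectrum, f, loss_fn,
                        scatter, settings):
    wl = _single_wavelength(spectrum)
    wl_m = wl / spectrum.n_medium
    dy, dx = grid.pitch(0)
    ny, nx = grid.shape
    scale = _ff_scale(dy, dx, wl_m, f)
    u1 = np.exp(1j * phase)
    u2 = scale * _centered_fft2(u1)
    focal_grid = SamplingGrid(ny, nx, wl_m * f / (ny * dy), wl_m * f / (nx * dx))
    pad = settings.pad_factor

    total = 0.0
    if scatter is None:
        g2 = np.zeros_like(u2)
        for z, target in targets:
            H = _ms_kernel(focal_grid, wl, spectrum.n_medium, float(z), settings)
            u3 = apply_transfer_page(u2, H, pad)
            val, dI = loss_fn(np.abs(u3) ** 2, target)
            total += val / len(targets)
            g3 = (dI / len(targets)) * u3
            g2 += apply_transfer_page(g3, H, pad, conjugate_kernel=True)
    else:
        H = _ms_kernel(focal_grid, wl, scatter.n_background, scatter.dz, settings)
        after_screen, after_step = _ms_forward(u2, scatter.dn, scatter.dz, wl,
                                               H, pad)
        injections = [None] * scatter.nz
        for z, target in targets:
            j = int(np.argmin(np.abs((np.arange(scatter.nz) + 1) * scatter.dz - z)))
            val, dI = loss_fn(np.abs(after_step[j]) ** 2, target)
            total += val / len(targets)
            inj = (dI / len(targets)) * after_step[j]
            injections[j] = inj if injections[j] is None else injections[j] + inj
        # backpropagate through the slices (no Δn gradient needed here)
        g = np.zeros_like(u2)
        k0dz = 2 * np.pi * scatter.dz / wl
        for j in range(scatter.nz - 1, -1, -1):
            if injections[j] is not None:
                g = g + injections[j]
            g_v = apply_transfer_page(g, H, pad, conjugate_kernel=True)
            g = g_v * np.exp(-1j * k0dz * scatter.dn[j])
        g2 = g
    g1 = ff_lens_adjoint_page(g2, dy, dx, wl_m, f)
    dphi = 2.0 * np.imag(np.conj(u1) * g1)
    return total, dphi


def optimize_cgh_phase(targets, grid: SamplingGrid, spectrum: Spectrum,
                       f: float, config: OptimizerConfig,
                       scatter: RefractiveIndexVolume | None = None,
                       settings: PropagationSettings = PropagationSettings(),
                       init_phase: np.ndarray | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Optimize an SLM phase so the hologram matches multi-plane targets.

    ``targets`` is a list of ``(z_plane_µm, intensity_image)`` pairs on
    the focal raster; with ``scatter`` the targets are matched against
    the corresponding multislice intensity planes inside the volume.
    Returns the phase map and the per-iteration loss trace.
    """
    targets = [(float(z), np.asarray(img, dtype=float)) for z, img in targets]
    if len(targets) == 0:
        raise ValueError("at least one target plane required")
    for _, img in targets:
        if img.shape != grid.shape:
            raise ValueError("target shape must match the grid")
    if config.loss not in ("neg-pearson", "accuracy", "mse"):
        raise ValueError("CGH supports mse, neg-pearson or accuracy losses")
    loss_fn = get_loss(config.loss)
    if init_phase is None:
        rng = np.random.default_rng(config.seed)
        init_phase = rng.uniform(0, 2 * np.pi, size=grid.shape)

    def value_and_grad(phi):
        return _cgh_value_and_grad(phi, targets, grid, spectrum, f, loss_fn,
                                   scatter, settings)

    return run_gradient_descent(value_and_grad, init_phase, config)


# ---------------------------------------------------------------------------
# Zernike aberration estimation


def _zernike_basis(grid: SamplingGrid, na: float, wavelength: float,
                   ansi_indices) -> np.ndarray:
    coords = pupil_coords(grid, na, wavelength)
    inside = coords.rho <= 1.0
    basis = np.stack([
        np.where(inside, zernike_polynomial(int(j), coords.rho, coords.theta), 0.0)
        for j in ansi_indices
    ])
    return basis


def _psf_forward(coeffs, basis, disk, defocus, ):
    """PSF stack from Zernike coefficients, returning intermediates."""
    phase_ab = 2 * np.pi * np.tensordot(coeffs, basis, axes=1)
    amps = []
    raw = np.empty((len(defocus),) + disk.shape)
    for i, dz_phase in enumerate(defocus):
        P = disk * np.exp(1j * (phase_ab + dz_phase))
        a = _centered_ifft2(P)
        amps.append((P, a))
        raw[i] = np.abs(a) ** 2
    return phase_ab, amps, raw


def estimate_zernike_coefficients(measured: np.ndarray, sample: np.ndarray,
                                  ansi_indices, config: OptimizerConfig,
                                  *, grid: SamplingGrid, spectrum: Spectrum,
                                  na: float, z_planes) -> np.ndarray:
    """Estimate pupil Zernike coefficients (waves) of a widefield system.

    Minimizes the configured loss between the forward-simulated volume —
    the known 3-D sample intensity convolved with the 3-D PSF generated
    by the candidate coefficients — and the measured volume.
    Coefficients start at zero.  Deterministic given init and config.
    """
    measured = np.asarray(measured, dtype=float)
    sample = np.asarray(sample, dtype=float)
    if measured.shape != sample.shape:
        raise ValueError("measured and sample volumes must have equal shapes")
    ansi_indices = [int(j) for j in np.atleast_1d(ansi_indices)]
    wl = _single_wavelength(spectrum)
    zs = [float(z) for z in np.atleast_1d(z_planes)]
    if len(zs) != sample.shape[0]:
        raise ValueError("one z plane per sample plane required")
    basis = _zernike_basis(grid, na, wl, ansi_indices)
    disk = pupil_disk(grid, na, wl)
    defocus = [defocus_phase(grid, wl / spectrum.n_medium, z) for z in zs]
    focus = int(np.argmin(np.abs(zs)))
    loss_fn = get_loss(config.loss)
    psf_shape = (len(zs),) + grid.shape

    def value_and_grad(c):
        phase_ab, amps, raw = _psf_forward(c, basis, disk, defocus)
        S = raw[focus].sum()
        psf = raw / S
        img = _conv_same(sample, psf)
        val, dimg = loss_fn(img, measured)
        dpsf = _conv_same_adjoint(dimg, sample, psf_shape, psf_shape)
        draw = dpsf / S
        draw[focus] -= np.sum(dpsf * psf) / S
        dphase = np.zeros(grid.shape)
        for i, (P, a) in enumerate(amps):
            ga = draw[i] * a
            gP = _cifft2_adjoint(ga)
            dphase += 2.0 * np.imag(np.conj(P) * gP)
        dc = 2 * np.pi * np.tensordot(basis, dphase, axes=([1, 2], [0, 1]))
        return val, dc

    coeffs, _ = run_gradient_descent(value_and_grad,
                                     np.zeros(len(ansi_indices)), config)
    return coeffs


# ---------------------------------------------------------------------------
# total variation proximal operator


def _tv_grad(u: np.ndarray) -> np.ndarray:
    g = np.zeros((u.ndim,) + u.shape)
    for d in range(u.ndim):
        sl = [slice(None)] * u.ndim
        sl[d] = slice(0, -1)
        g[d][tuple(sl)] = np.diff(u, axis=d)
    return g


def _tv_div(p: np.ndarray) -> np.ndarray:
    out = np.zeros(p.shape[1:])
    for d in range(out.ndim):
        pd = p[d]
        sl_first = [slice(None)] * out.ndim
        sl_first[d] = slice(0, 1)
        sl_last = [slice(None)] * out.ndim
        sl_last[d] = slice(-1, None)
        dd = np.diff(pd, axis=d)
        sl_mid = [slice(None)] * out.ndim
        sl_mid[d] = slice(1, None)
        out[tuple(sl_mid)] += dd
        out[tuple(sl_first)] += pd[tuple(sl_first)]
        # note: last forward difference is zero by construction, so the
        # boundary term -p[last] never appears with these gradients
    return out


def total_variation(u: np.ndarray) -> float:
    """Discrete isotropic total variation (forward differences)."""
    g = _tv_grad(np.asarray(u, dtype=float))
    return float(np.sum(np.sqrt(np.sum(g * g, axis=0))))


def tv_prox(volume: np.ndarray, weight: float, tol: float = 1e-4,
            max_iter: int = 500) -> np.ndarray:
    """Proximal map of isotropic total variation (dual projection method).

    Solves ``argmin_u ½‖u − volume‖² + weight·TV(u)`` by iterating on
    the dual variable, stopping when the relative change of the primal
    iterate drops to ``tol`` (default 1e-4).
    """
    x = np.asarray(volume, dtype=float)
    if weight < 0:
        raise ValueError("weight must be nonnegative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if weight == 0:
        return x.copy()
    tau = 1.0 / (4.0 * x.ndim)
    p = np.zeros((x.ndim,) + x.shape)
    u_prev = x.copy()
    for _ in range(max_iter):
        q = _tv_grad(_tv_div(p) - x / weight)
        qn = np.sqrt(np.sum(q * q, axis=0))
        p = (p + tau * q) / (1.0 + tau * qn)
        u = x - weight * _tv_div(p)
        num = np.linalg.norm(u - u_prev)
        den = max(np.linalg.norm(u_prev), 1e-30)
        u_prev = u
        if num / den <= tol:
            break
    return u_prev


# ---------------------------------------------------------------------------
# refractive-index tomography


def reconstruct_refractive_index(
    measurements, angles, *, grid: SamplingGrid, nz: int, dz: float,
    spectrum: Spectrum, config: OptimizerConfig, tv_weight: float,
    n_background: float = 1.0,
    settings: PropagationSettings = PropagationSettings(pad_factor=1),
) -> tuple[RefractiveIndexVolume, np.ndarray]:
    """Multi-angle intensity tomography of the index contrast Δn.

    For every illumination angle the forward model is a tilted plane
    wave propagated through the candidate volume by multislice beam
    propagation; the data term is the MSE between the simulated and
    measured exit-plane intensities.  Δn starts at zero; each epoch
    performs one gradient step per angle, then smooths with the TV
    proximal operator (relative error 1e-4), and combines successive
    smoothed iterates with the Nesterov momentum sequence
    ``t_{k+1} = (1 + √(1 + 4 t_k²)) / 2``.

    ``config.iterations`` counts epochs and ``config.step_size`` is the
    plain gradient-descent step per angle.  Returns the reconstructed
    volume and the per-epoch data-loss trace.
    """
    measurements = [np.asarray(m, dtype=float) for m in measurements]
    angles = [tuple(a) for a in angles]
    if len(measurements) != len(angles):
        raise ValueError("one illumination angle per measurement required")
    for m in measurements:
        if m.shape != grid.shape:
            raise ValueError("measurement shapes must match the grid")
    wl = _single_wavelength(spectrum)
    H = _ms_kernel(grid, wl, n_background, dz, settings)
    pad = settings.pad_factor
    in_pages = [create_plane_wave(grid, spectrum, 1.0, ang).u[0]
                for ang in angles]

    shape = (nz,) + grid.shape
    x_prev = np.zeros(shape)
    y = np.zeros(shape)
    t_k = 1.0
    trace = np.empty(config.iterations)
    for epoch in range(config.iterations):
        total = 0.0
        for page, meas in zip(in_pages, measurements):
            after_screen, after_step = _ms_forward(page, y, dz, wl, H, pad)
            exit_page = after_step[-1]
            val, dI = ((np.mean((np.abs(exit_page) ** 2 - meas) ** 2)),
                       2.0 * (np.abs(exit_page) ** 2 - meas) / meas.size)
            total += val
            g_final = dI * exit_page
            ddn = _ms_backward_dn(after_screen, y, dz, wl, H, pad, g_final)
            y = y - config.step_size * ddn
        trace[epoch] = total / len(measurements)
        x_new = tv_prox(y, tv_weight, tol=1e-4)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k)) / 2.0
        y = x_new + ((t_k - 1.0) / t_next) * (x_new - x_prev)
        x_prev = x_new
        t_k = t_next
    volume = RefractiveIndexVolume(dn=x_prev, dz=dz, grid=grid,
                                   n_background=n_background)
    return volume, trace


# ---------------------------------------------------------------------------
# ring deconvolution


def ring_deconvolve(measured: np.ndarray, psfs: RadialPSFSet,
                    config: OptimizerConfig,
                    n_phi: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Spatially-varying deconvolution under the ring-convolution model.

    The estimate is initialized to the measured image and updated by
    Adam on the MSE between its ring-convolved image and the
    measurement, with a nonnegativity clip after each step.  Returns the
    estimate and the loss trace.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 2:
        raise ValueError("measured image must be 2-D")
    op = RingOperator(psfs, measured.shape, n_phi=n_phi)
    loss_fn = get_loss(config.loss)

    def value_and_grad(x):
        sim = op.apply(x)
        val, dI = loss_fn(sim, measured)
        return val, op.adjoint(dI)

    return run_gradient_descent(value_and_grad, measured, config,
                                projection=lambda x: np.maximum(x, 0.0))


# ---------------------------------------------------------------------------
# canned gradient checks (CLI + acceptance surface)


def gradcheck_element_chain(seed: int = 0, n: int = 32,
                            rel_step: float = 1e-6) -> GradientReport:
    """Finite-difference check of an element-chain gradient.

    Loss: total power after plane wave → phase mask → propagation
    (100 µm) → Fourier lens → propagation (f), differentiated with
    respect to the mask pixels.  (The chain's maps are unitary, so the
    power is constant in exact arithmetic — but not pixelwise linear;
    the test exercises the full adjoint chain.)  To keep the loss
    nontrivially dependent on the mask, a fixed off-center absorbing
    aperture is inserted before the lens.
    """
    rng = np.random.default_rng(seed)
    grid = SamplingGrid(n, n, 1.0, 1.0)
    spectrum = Spectrum.monochromatic(0.5)
    wl = spectrum.wavelengths[0]
    dy, dx = 1.0, 1.0
    f = 5000.0
    settings = PropagationSettings(pad_factor=2)
    H1 = _ms_kernel(grid, wl, 1.0, 100.0, settings)
    # absorbing mask breaking unitarity so power depends on the phase
    yy, xx = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                         indexing="ij")
    absorber = np.exp(-((yy - 4) ** 2 + (xx + 3) ** 2) / (2 * (n / 6) ** 2))
    scale = _ff_scale(dy, dx, wl, f)
    ny = nx = n
    focal_grid = SamplingGrid(ny, nx, wl * f / (ny * dy), wl * f / (nx * dx))
    H2 = _ms_kernel(focal_grid, wl, 1.0, f, settings)
    d2y, d2x = focal_grid.pitch(0)

    def forward(phi):
        u1 = np.exp(1j * phi)
        u2 = apply_transfer_page(u1, H1, 2) * absorber
        u3 = scale * _centered_fft2(u2)
        u4 = apply_transfer_page(u3, H2, 2)
        return u1, u2, u3, u4

    def loss(phi):
        u4 = forward(phi)[3]
        return float(np.sum(np.abs(u4) ** 2) * d2y * d2x)

    def grad(phi):
        u1, u2, u3, u4 = forward(phi)
        g4 = u4 * (d2y * d2x)
        g3 = apply_transfer_page(g4, H2, 2, conjugate_kernel=True)
        g2 = ff_lens_adjoint_page(g3, dy, dx, wl, f) * absorber
        g1 = apply_transfer_page(g2, H1, 2, conjugate_kernel=True)
        return 2.0 * np.imag(np.conj(u1) * g1)

    point = rng.uniform(0, 2 * np.pi, size=(n, n))
    return gradcheck_fd(loss, grad, point, rel_step=rel_step, seed=seed)


def gradcheck_multislice(seed: int = 0, n: int = 16, nz: int = 4,
                         rel_step: float = 1e-6) -> GradientReport:
    """Finite-difference check of the multislice Δn gradient.

    Loss: MSE between the multislice intensity stack and a fixed random
    target, differentiated with respect to the Δn voxels.
    """
    rng = np.random.default_rng(seed)
    grid = SamplingGrid(n, n, 0.5, 0.5)
    spectrum = Spectrum.monochromatic(0.66)
    wl = spectrum.wavelengths[0]
    dz = 1.0
    settings = PropagationSettings(pad_factor=1)
    H = _ms_kernel(grid, wl, 1.0, dz, settings)
    page = create_plane_wave(grid, spectrum).u[0]
    target = rng.uniform(0.5, 1.5, size=(nz, n, n))
    point = 0.01 * rng.standard_normal((nz, n, n))

    def loss(dn):
        _, after_step = _ms_forward(page, dn, dz, wl, H, 1)
        stack = np.stack([np.abs(u) ** 2 for u in after_step])
        return float(np.mean((stack - target) ** 2))

    def grad(dn):
        after_screen, after_step = _ms_forward(page, dn, dz, wl, H, 1)
        stack = np.stack([np.abs(u) ** 2 for u in after_step])
        dI = 2.0 * (stack - target) / stack.size
        injections = [dI[j] * after_step[j] for j in range(nz)]
        g0 = np.zeros_like(page)
        return _ms_backward_dn(after_screen, dn, dz, wl, H, 1, g0,
                               injections=injections)

    return gradcheck_fd(loss, grad, point, rel_step=rel_step, seed=seed)
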