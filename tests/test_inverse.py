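import numpy as np
import pytest

import wavekit as wk
from wavekit.imaging import simulate_psf_stack_4f, incoherent_image_3d
from wavekit.inverse import (
    estimate_zernike_coefficients,
    gerchberg_saxton,
    gradcheck_element_chain,
    gradcheck_multislice,
    optimize_cgh_phase,
    reconstruct_refractive_index,
    ring_deconvolve,
    simulate_cgh_planes,
    total_variation,
    tv_prox,
)
from wavekit.optim import OptimizerConfig
from wavekit.scattering import RefractiveIndexVolume
from conftest import rel_l2


class TestDifferentiabilityContract:
    def test_element_chain_gradient(self):
        report = gradcheck_element_chain(seed=0)
        assert report.max_rel_error <= 1e-5

    def test_multislice_gradient(self):
        report = gradcheck_multislice(seed=0)
        assert report.max_rel_error <= 1e-4


class TestGerchbergSaxton:
    def setup_method(self):
        self.grid = wk.SamplingGrid(64, 64, 10.0, 10.0)
        self.spectrum = wk.Spectrum.monochromatic(0.5)
        self.f = 200000.0

    def achievable_target(self, seed=0):
        from wavekit.elements import _centered_fft2, _ff_scale
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0, 2 * np.pi, (64, 64))
        scale = _ff_scale(10.0, 10.0, 0.5, self.f)
        return np.abs(scale * _centered_fft2(np.exp(1j * phi)))

    def test_achievable_target_recovered(self):
        # achievable speckle target from an independent random start;
        # alternating projections converge slowly, so allow 1000 rounds
        target = self.achievable_target()
        _, errors = gerchberg_saxton(target, self.grid, self.spectrum,
                                     self.f, 1000, seed=1)
        assert errors[-1] <= 1e-2

    def test_error_trace_non_increasing(self):
        target = self.achievable_target(seed=2)
        _, errors = gerchberg_saxton(target, self.grid, self.spectrum,
                                     self.f, 30, seed=3)
        assert np.all(np.diff(errors) <= 1e-12)

    def test_phase_in_principal_range(self):
        phi, _ = gerchberg_saxton(self.achievable_target(), self.grid,
                                  self.spectrum, self.f, 5)
        assert phi.min() >= 0.0 and phi.max() < 2 * np.pi

    def test_all_zero_target_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gerchberg_saxton(np.zeros((64, 64)), self.grid, self.spectrum,
                             self.f, 10)


class TestCGH:
    def setup_method(self):
        self.grid = wk.SamplingGrid(32, 32, 10.0, 10.0)
        self.spectrum = wk.Spectrum.monochromatic(0.5)
        self.f = 200000.0

    def test_canonical_three_plane_configuration(self):
        # planes at -10, 0, +10 mm from the lens focal plane
        rng = np.random.default_rng(5)
        true_phase = rng.uniform(0, 2 * np.pi, (32, 32))
        zs = (-10000.0, 0.0, 10000.0)
        targets = [(z, simulate_cgh_planes(true_phase, self.grid,
                                           self.spectrum, self.f, [z])[0])
                   for z in zs]
        cfg = OptimizerConfig(step_size=0.1, iterations=30,
                              loss="neg-pearson", seed=0)
        phase, trace = optimize_cgh_phase(targets, self.grid, self.spectrum,
                                          self.f, cfg)
        assert phase.shape == (32, 32)
        assert trace[-1] <= trace[0]

    def test_loss_decreases(self):
        rng = np.random.default_rng(6)
        target = rng.random((32, 32))
        cfg = OptimizerConfig(step_size=0.1, iterations=40, loss="mse", seed=1)
        _, trace = optimize_cgh_phase([(0.0, target)], self.grid,
                                      self.spectrum, self.f, cfg)
        assert trace[-1] <= trace[0]

    def test_through_scattering_loss_decreases(self):
        rng = np.random.default_rng(7)
        wl_m = 0.5
        dy2 = wl_m * self.f / (32 * 10.0)
        focal_grid = wk.SamplingGrid(32, 32, dy2, dy2)
        dn = 0.005 * rng.standard_normal((4, 32, 32))
        scatter = RefractiveIndexVolume(dn=dn, dz=50.0, grid=focal_grid)
        target = rng.random((32, 32))
        cfg = OptimizerConfig(step_size=0.1, iterations=25,
                              loss="neg-pearson", seed=2)
        _, trace = optimize_cgh_phase([(200.0, target)], self.grid,
                                      self.spectrum, self.f, cfg,
                                      scatter=scatter)
        assert trace[-1] <= trace[0]

    def test_target_shape_mismatch_rejected(self):
        cfg = OptimizerConfig(step_size=0.1, iterations=5, loss="mse")
        with pytest.raises(ValueError, match="shape"):
            optimize_cgh_phase([(0.0, np.zeros((16, 16)))], self.grid,
                               self.spectrum, self.f, cfg)

    def test_quantized_evaluation_uses_256_levels(self):
        rng = np.random.default_rng(8)
        phase = rng.uniform(0, 2 * np.pi, (32, 32))
        out = simulate_cgh_planes(phase, self.grid, self.spectrum, self.f,
                                  [0.0], quantize_bits=8)
        assert len(out) == 1 and out[0].shape == (32, 32)


class TestZernikeEstimation:
    def setup_method(self):
        self.nz, self.n = 8, 32
        self.grid = wk.SamplingGrid(self.n, self.n, 0.2, 0.2)
        self.spectrum = wk.Spectrum.monochromatic(0.513)
        self.na = 0.8
        self.zs = (np.arange(self.nz) - self.nz // 2) * 0.5
        rng = np.random.default_rng(0)
        self.sample = np.zeros((self.nz, self.n, self.n))
        pts = rng.integers(2, self.n - 2, size=(12, 2))
        zpts = rng.integers(1, self.nz - 1, size=12)
        self.sample[zpts, pts[:, 0], pts[:, 1]] = rng.uniform(0.5, 1.0, 12)

    def measure(self, spec):
        ab = None
        if spec is not None:
            ab = wk.zernike_phase_map(self.grid, self.na, spec, 0.513)
        psf = simulate_psf_stack_4f(self.na, ab, self.zs, self.grid,
                                    self.spectrum)
        return incoherent_image_3d(self.sample, psf)

    def test_null_recovery(self):
        measured = self.measure(None)
        cfg = OptimizerConfig(step_size=0.01, iterations=40, loss="mse")
        c = estimate_zernike_coefficients(measured, self.sample, [5, 6, 7],
                                          cfg, grid=self.grid,
                                          spectrum=self.spectrum, na=self.na,
                                          z_planes=self.zs)
        assert np.max(np.abs(c)) <= 0.005

    def test_small_scale_recovery(self):
        true = wk.ZernikeSpec((5, 6), (0.2, -0.15))
        measured = self.measure(true)
        cfg = OptimizerConfig(step_size=0.02, iterations=120, loss="mse")
        c = estimate_zernike_coefficients(measured, self.sample, [5, 6], cfg,
                                          grid=self.grid,
                                          spectrum=self.spectrum, na=self.na,
                                          z_planes=self.zs)
        assert np.sqrt(np.mean((c - [0.2, -0.15]) ** 2)) <= 0.01

    def test_deterministic(self):
        measured = self.measure(wk.ZernikeSpec((5,), (0.1,)))
        cfg = OptimizerConfig(step_size=0.02, iterations=10, loss="mse")
        kwargs = dict(grid=self.grid, spectrum=self.spectrum, na=self.na,
                      z_planes=self.zs)
        c1 = estimate_zernike_coefficients(measured, self.sample, [5], cfg,
                                           **kwargs)
        c2 = estimate_zernike_coefficients(measured, self.sample, [5], cfg,
                                           **kwargs)
        assert np.array_equal(c1, c2)

    def test_shape_mismatch_rejected(self):
        cfg = OptimizerConfig(step_size=0.01, iterations=5, loss="mse")
        with pytest.raises(ValueError, match="shape"):
            estimate_zernike_coefficients(np.zeros((2, 8, 8)), self.sample,
                                          [5], cfg, grid=self.grid,
                                          spectrum=self.spectrum, na=self.na,
                                          z_planes=self.zs)


class TestTVProx:
    def test_zero_weight_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((6, 7, 8))
        assert np.array_equal(tv_prox(v, 0.0), v)

    def test_constant_volume_unchanged(self):
        v = np.full((5, 6, 7), 3.2)
        assert np.allclose(tv_prox(v, 1.0), v)

    def test_total_variation_never_increases(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((6, 8, 8))
        for weight in (0.05, 0.3, 1.0):
            assert total_variation(tv_prox(v, weight)) <= total_variation(v)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            tv_prox(np.zeros((2, 2, 2)), -0.1)


class TestRefractiveIndexReconstruction:
    def setup_method(self):
        self.nz, self.n = 8, 24
        self.grid = wk.SamplingGrid(self.n, self.n, 0.5, 0.5)
        self.spectrum = wk.Spectrum.monochromatic(0.66)
        self.angles = [(np.deg2rad(a), 0.0) for a in (-20, 20)] + \
                      [(0.0, np.deg2rad(a)) for a in (-20, 20)]
        self.settings = wk.PropagationSettings(pad_factor=1)

    def measure(self, dn):
        vol = RefractiveIndexVolume(dn=dn, dz=1.0, grid=self.grid)
        out = []
        for ang in self.angles:
            f = wk.create_plane_wave(self.grid, self.spectrum, 1.0, ang)
            out.append(wk.multislice_propagate(f, vol,
                                               self.settings).intensity())
        return out

    def test_null_phantom_recovers_zero(self):
        meas = self.measure(np.zeros((self.nz, self.n, self.n)))
        cfg = OptimizerConfig(step_size=0.01, iterations=10, loss="mse")
        rec, trace = reconstruct_refractive_index(
            meas, self.angles, grid=self.grid, nz=self.nz, dz=1.0,
            spectrum=self.spectrum, config=cfg, tv_weight=1e-5,
            settings=self.settings)
        assert np.max(np.abs(rec.dn)) <= 1e-4

    def test_sphere_phantom_recovery_correlates(self):
        zz, yy, xx = np.meshgrid(np.arange(self.nz) - 4,
                                 np.arange(self.n) - 12,
                                 np.arange(self.n) - 12, indexing="ij")
        truth = np.where(zz ** 2 + (yy / 2) ** 2 + (xx / 2) ** 2 <= 9,
                         0.02, 0.0)
        meas = self.measure(truth)
        cfg = OptimizerConfig(step_size=0.01, iterations=25, loss="mse")
        rec, trace = reconstruct_refractive_index(
            meas, self.angles, grid=self.grid, nz=self.nz, dz=1.0,
            spectrum=self.spectrum, config=cfg, tv_weight=3e-5,
            settings=self.settings)
        r = np.corrcoef(rec.dn.ravel(), truth.ravel())[0, 1]
        assert r >= 0.5
        # data loss is non-increasing over the back half of the run
        back = trace[len(trace) // 2:]
        assert np.all(np.diff(back) <= 0.05 * back[:-1])

    def test_angle_count_mismatch_rejected(self):
        cfg = OptimizerConfig(step_size=0.01, iterations=2, loss="mse")
        with pytest.raises(ValueError, match="angle"):
            reconstruct_refractive_index(
                [np.zeros((self.n, self.n))], self.angles, grid=self.grid,
                nz=self.nz, dz=1.0, spectrum=self.spectrum, config=cfg,
                tv_weight=1e-5)


class TestRingDeconvolve:
    def test_delta_psfs_are_identity_after_one_iteration(self):
        # single-pixel PSFs: the ring operator is the identity, the loss
        # starts at zero and the estimate stays the measurement
        patch = np.zeros((5, 33, 33))
        patch[:, 16, 16] = 1.0
        psfs = wk.RadialPSFSet(psfs=patch, radii=(0.0, 8.0, 16.0, 24.0, 32.0),
                               grid=wk.SamplingGrid(33, 33, 1.0, 1.0))
        rng = np.random.default_rng(0)
        measured = rng.random((48, 48))
        cfg = OptimizerConfig(step_size=0.01, iterations=1, loss="mse")
        est, trace = ring_deconvolve(measured, psfs, cfg)
        assert np.max(np.abs(est - measured)) <= 1e-8

    def test_point_sources_relocalized(self, radial_psfs_64):
        rng = np.random.default_rng(0)
        s = np.zeros((64, 64))
        pts = []
        while len(pts) < 10:
            iy, ix = rng.integers(8, 56, 2)
            if all(abs(iy - a) + abs(ix - b) > 6 for a, b in pts):
                pts.append((iy, ix))
                s[iy, ix] = rng.uniform(0.5, 1.0)
        measured = wk.sv_superposition_oracle(s, radial_psfs_64)
        cfg = OptimizerConfig(step_size=0.005, iterations=200, loss="mse")
        est, trace = ring_deconvolve(measured, radial_psfs_64, cfg)
        assert trace[-1] <= trace[0]
        for iy, ix in pts:
            window = est[iy - 1:iy + 2, ix - 1:ix + 2]
            hood = est[iy - 3:iy + 4, ix - 3:ix + 4]
            assert window.max() >= hood.max() - 1e-12

    def test_shape_mismatch_rejected(self, radial_psfs_64):
        cfg = OptimizerConfig(step_size=0.01, iterations=1, loss="mse")
        with pytest.raises(ValueError):
            ring_deconvolve(np.zeros((3, 4, 5)), radial_psfs_64, cfg)
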