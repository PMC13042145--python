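import numpy as np
import pytest

import wavekit as wk
from wavekit.elements import ansi_to_nm
from conftest import rel_l2


class TestPhaseMask:
    def test_zero_phase_is_identity(self, grid64, mono_spectrum):
        f = wk.create_plane_wave(grid64, mono_spectrum)
        out = wk.apply_phase_mask(f, np.zeros((64, 64)))
        assert np.array_equal(out.u, f.u)

    def test_pi_phase_negates(self, grid64, mono_spectrum):
        f = wk.create_plane_wave(grid64, mono_spectrum)
        out = wk.apply_phase_mask(f, np.full((64, 64), np.pi))
        assert np.allclose(out.u, -f.u)

    def test_modulus_preserved(self, grid64, mono_spectrum):
        rng = np.random.default_rng(0)
        f = wk.create_plane_wave(grid64, mono_spectrum, tilt=(0.01, 0.02))
        out = wk.apply_phase_mask(f, rng.uniform(-9, 9, (64, 64)))
        assert np.max(np.abs(np.abs(out.u) - np.abs(f.u))) <= 1e-12

    def test_shape_mismatch_rejected(self, grid64, mono_spectrum):
        f = wk.create_plane_wave(grid64, mono_spectrum)
        with pytest.raises(ValueError, match="shape"):
            wk.apply_phase_mask(f, np.zeros((32, 32)))


class TestThinLens:
    def test_infinite_focal_length_limit(self, gaussian_field):
        out = wk.thin_lens(gaussian_field, 1e12)
        assert rel_l2(out.u, gaussian_field.u) <= 1e-6

    def test_zero_focal_length_rejected(self, gaussian_field):
        with pytest.raises(ValueError):
            wk.thin_lens(gaussian_field, 0.0)

    def test_plane_wave_focuses_to_central_pixel(self):
        # high Fresnel number so the focal spot is a clean on-axis peak
        grid = wk.SamplingGrid(512, 512, 1.0, 1.0)
        f = wk.create_plane_wave(grid, wk.Spectrum.monochromatic(0.5))
        ap = wk.circular_pupil(f, 400.0, domain="spatial")
        foc = wk.propagate_angular_spectrum(wk.thin_lens(ap, 5000.0), 5000.0)
        intensity = foc.intensity()
        assert np.unravel_index(np.argmax(intensity), intensity.shape) == (256, 256)

    def test_airy_first_dark_ring_radius(self):
        # D = 1000 µm, f = 50 000 µm, λ = 0.5 µm → 1.22 λ f / D = 30.5 µm
        grid = wk.SamplingGrid(1024, 1024, 2.0, 2.0)
        f0 = wk.create_plane_wave(grid, wk.Spectrum.monochromatic(0.5))
        ap = wk.circular_pupil(f0, 1000.0, domain="spatial")
        foc = wk.propagate_angular_spectrum(wk.thin_lens(ap, 50000.0), 50000.0)
        profile = foc.intensity()[512, 512:]
        mins = [i for i in range(1, 200)
                if profile[i] < profile[i - 1] and profile[i] <= profile[i + 1]]
        assert abs(mins[0] * 2.0 - 30.5) <= 2.0  # within one output pixel


class TestCircularPupil:
    def test_oversized_aperture_is_identity(self, gaussian_field):
        out = wk.circular_pupil(gaussian_field, 10000.0, domain="spatial")
        assert np.array_equal(out.u, gaussian_field.u)

    @pytest.mark.parametrize("domain,cutoff", [("spatial", 40.0),
                                               ("frequency", 0.2)])
    def test_power_never_increases(self, gaussian_field, domain, cutoff):
        out = wk.circular_pupil(gaussian_field, cutoff, domain=domain)
        assert out.power() <= gaussian_field.power() * (1 + 1e-12)

    @pytest.mark.parametrize("domain,cutoff", [("spatial", 40.0),
                                               ("frequency", 0.2)])
    def test_idempotent(self, gaussian_field, domain, cutoff):
        once = wk.circular_pupil(gaussian_field, cutoff, domain=domain)
        twice = wk.circular_pupil(once, cutoff, domain=domain)
        assert rel_l2(twice.u, once.u) <= 1e-12

    def test_invalid_domain_rejected(self, gaussian_field):
        with pytest.raises(ValueError, match="domain"):
            wk.circular_pupil(gaussian_field, 1.0, domain="angular")


class TestZernike:
    @pytest.mark.parametrize("j,nm", [(0, (0, 0)), (1, (1, -1)), (2, (1, 1)),
                                      (3, (2, -2)), (4, (2, 0)), (5, (2, 2)),
                                      (12, (4, 0)), (14, (4, 4))])
    def test_ansi_index_table(self, j, nm):
        assert ansi_to_nm(j) == nm

    def test_piston_is_constant(self, grid64):
        spec = wk.ZernikeSpec((0,), (0.7,))
        phase = wk.zernike_phase_map(grid64, 0.25, spec, 0.5)
        coords = wk.pupil_coords(grid64, 0.25, 0.5)
        inside = coords.rho <= 1.0
        assert np.allclose(phase[inside], 2 * np.pi * 0.7)
        assert np.all(phase[~inside] == 0.0)

    def test_defocus_value_at_pupil_edge(self):
        # ANSI 4 (defocus): Z = 2ρ² − 1 → 1 at ρ = 1
        assert wk.zernike_polynomial(4, np.array([1.0]), np.array([0.0]))[0] \
            == pytest.approx(1.0)
        assert wk.zernike_polynomial(4, np.array([0.0]), np.array([0.0]))[0] \
            == pytest.approx(-1.0)

    def test_discrete_orthogonality_on_unit_disk(self):
        n = 512
        yy, xx = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n),
                             indexing="ij")
        rho = np.hypot(yy, xx)
        theta = np.arctan2(yy, xx)
        disk = rho <= 1.0
        z3 = wk.zernike_polynomial(3, rho, theta) * disk
        z4 = wk.zernike_polynomial(4, rho, theta) * disk
        cross = abs(np.sum(z3 * z4))
        assert cross / (np.linalg.norm(z3) * np.linalg.norm(z4)) <= 1e-3

    def test_phase_map_linear_in_coefficients(self, grid64):
        s1 = wk.ZernikeSpec((4, 7), (0.3, -0.1))
        s2 = wk.ZernikeSpec((4, 7), (0.6, -0.2))
        p1 = wk.zernike_phase_map(grid64, 0.25, s1, 0.5)
        p2 = wk.zernike_phase_map(grid64, 0.25, s2, 0.5)
        assert np.allclose(p2, 2 * p1)

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            wk.ZernikeSpec((-1,), (0.1,))


class TestSeidel:
    def pupil(self, field_point):
        grid = wk.SamplingGrid(64, 64, 1.0, 1.0)
        return wk.pupil_coords(grid, 0.25, 0.5, field_point=field_point)

    def test_zero_coefficients_zero_phase(self):
        phase = wk.seidel_phase_map(self.pupil((0.7, 0.2)),
                                    wk.SeidelSpec((0, 0, 0, 0, 0)))
        assert np.all(phase == 0.0)

    def test_on_axis_only_spherical_survives(self):
        spec = wk.SeidelSpec((0.5, 0.9, 0.8, 0.7, 0.6))
        coords = self.pupil((0.0, 0.0))
        phase = wk.seidel_phase_map(coords, spec)
        expected = 2 * np.pi * 0.5 * coords.rho ** 4
        assert np.allclose(phase, expected)

    def test_calibrated_coefficients_term_sum(self, strong_seidel):
        # h = 1, ρ = 1, θ = 0: W = 0.85+0.56+0.25+0.29+0 = 1.95 waves
        coords = wk.PupilCoords(rho=np.array([1.0]), theta=np.array([0.0]),
                                field_point=(1.0, 0.0))
        phase = wk.seidel_phase_map(coords, strong_seidel)
        assert phase[0] == pytest.approx(2 * np.pi * 1.95)

    def test_linear_in_coefficients(self):
        coords = self.pupil((0.5, 0.3))
        p1 = wk.seidel_phase_map(coords, wk.SeidelSpec((0.1, 0.2, 0.3, 0.4, 0.5)))
        p2 = wk.seidel_phase_map(coords, wk.SeidelSpec((0.2, 0.4, 0.6, 0.8, 1.0)))
        assert np.allclose(p2, 2 * p1)

    def test_rotating_field_point_rotates_pupil_map(self, strong_seidel):
        # 90° rotation is exact on an odd square raster (symmetric frequencies)
        grid = wk.SamplingGrid(65, 65, 1.0, 1.0)
        p_x = wk.seidel_phase_map(
            wk.pupil_coords(grid, 0.25, 0.5, field_point=(0.8, 0.0)),
            strong_seidel)
        p_y = wk.seidel_phase_map(
            wk.pupil_coords(grid, 0.25, 0.5, field_point=(0.0, 0.8)),
            strong_seidel)
        rotations = [np.rot90(p_x, k) for k in (1, -1)]
        assert any(np.allclose(p_y, r, atol=1e-10) for r in rotations)


class TestQuantizePhase:
    def test_eight_bit_half_step_bound(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-10, 10, (128, 128))
        q = wk.quantize_phase(phase, 8)
        wrapped = np.mod(phase, 2 * np.pi)
        err = np.abs(q - wrapped)
        err = np.minimum(err, 2 * np.pi - err)  # level 0 wraps to 2π
        assert len(np.unique(q)) <= 256
        assert err.max() <= np.pi / 256 + 1e-12

    def test_one_bit_levels(self):
        q = wk.quantize_phase(np.linspace(-7, 7, 1001), 1)
        assert set(np.unique(q)) <= {0.0, np.pi}

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(0, 2 * np.pi, (32, 32))
        q = wk.quantize_phase(phase, 6)
        assert np.array_equal(wk.quantize_phase(q, 6), q)

    @pytest.mark.parametrize("bits", [0, 17])
    def test_bits_out_of_range(self, bits):
        with pytest.raises(ValueError):
            wk.quantize_phase(np.zeros(4), bits)


class TestFourierLens:
    def test_plane_wave_concentrates_at_center(self, mono_spectrum):
        grid = wk.SamplingGrid(128, 128, 1.0, 1.0)
        f = wk.create_plane_wave(grid, mono_spectrum)
        out = wk.ff_lens_to_focal_plane(f, 100000.0)
        intensity = out.intensity()
        assert intensity[63:66, 63:66].sum() / intensity.sum() >= 0.99

    def test_output_pitch_formula(self):
        grid = wk.SamplingGrid(512, 512, 10.0, 10.0)
        f = wk.create_plane_wave(grid, wk.Spectrum.monochromatic(0.5))
        out = wk.ff_lens_to_focal_plane(f, 200000.0)
        assert out.grid.pitch(0)[1] == pytest.approx(0.5 * 200000 / (512 * 10))

    def test_power_conserved(self, gaussian_field):
        out = wk.ff_lens_to_focal_plane(gaussian_field, 50000.0)
        assert abs(out.power() - gaussian_field.power()) \
            <= 1e-10 * gaussian_field.power()

    def test_inverse_roundtrip(self, gaussian_field):
        out = wk.ff_lens_to_focal_plane(gaussian_field, 50000.0)
        back = wk.ff_lens_inverse(out, 50000.0, gaussian_field.grid)
        assert rel_l2(back.u, gaussian_field.u) <= 1e-12

    def test_matches_thin_lens_plus_propagation(self):
        # f = N dx²/λ makes both output rasters coincide
        n, dx, wl = 128, 1.0, 0.5
        f = n * dx ** 2 / wl
        grid = wk.SamplingGrid(n, n, dx, dx)
        y, x = grid.coords()
        u = np.exp(-(y[:, None] ** 2 + x[None, :] ** 2) / 10.0 ** 2)
        field = wk.Field(u=u[None], grid=grid,
                         spectrum=wk.Spectrum.monochromatic(wl))
        via_lens = wk.propagate_angular_spectrum(wk.thin_lens(field, f), f)
        via_ft = wk.ff_lens_to_focal_plane(field, f)
        assert rel_l2(via_lens.intensity(), via_ft.intensity()) <= 0.02
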