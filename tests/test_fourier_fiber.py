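import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiofiber import phantoms
from cardiofiber.fourier_fiber import (
    analyze_volume,
    anisotropy_fa,
    canonical_axial,
    cone_background,
    eigendecompose,
    fa_squared,
    fiber_distance,
    fiber_orientation,
    kb_window,
    radial_profile,
    reciprocal_anisotropy,
    spectral_covariance,
    windowed_power_spectrum,
)
from cardiofiber.volume_io import AnalysisConfig, Volume3D

from conftest import axial_angle_deg


def i0_series(x, terms=60):
    """Zero-order modified Bessel function by its power series (oracle)."""
    import math

    total = 0.0
    for n in range(terms):
        total += (x / 2.0) ** (2 * n) / (math.factorial(n)) ** 2
    return total


class TestKaiserBesselWindow:
    def test_center_value_is_one(self):
        w = kb_window(48, 8.0)
        assert w.profile[24] == pytest.approx(1.0, abs=1e-14)
        assert w.weights[24, 24, 24] == pytest.approx(1.0, abs=1e-13)
        assert w.weights.max() <= 1.0 + 1e-13

    def test_beta_zero_is_flat(self):
        w = kb_window(16, 0.0)
        np.testing.assert_allclose(w.weights, 1.0)

    def test_edge_value_matches_bessel_series(self):
        # oracle: I0(8) evaluated by its power series
        w = kb_window(48, 8.0)
        assert w.profile[0] == pytest.approx(1.0 / i0_series(8.0), rel=1e-10)
        assert w.profile[0] == pytest.approx(2.34e-3, rel=0.01)

    def test_strictly_positive_and_separable(self):
        w = kb_window(12, 5.0)
        assert np.all(w.weights > 0)
        outer = (w.profile[:, None, None] * w.profile[None, :, None]
                 * w.profile[None, None, :])
        np.testing.assert_allclose(w.weights, outer)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            kb_window(4, 8.0)
        with pytest.raises(ValueError):
            kb_window(16, -1.0)


class TestWindowedPowerSpectrum:
    def test_constant_cube_gives_zero_spectrum(self):
        w = kb_window(16, 8.0)
        spec = windowed_power_spectrum(np.full((16, 16, 16), 2.0), w)
        assert np.all(spec == 0.0)

    def test_cosine_mass_at_expected_bin(self):
        l = 48
        x = np.arange(l)
        cube = np.broadcast_to(np.cos(2 * np.pi * x / 12.0),
                               (l, l, l)).copy()
        w = kb_window(l, 8.0)
        spec = windowed_power_spectrum(cube, w)
        qx = np.fft.fftfreq(l)
        # mass within one bin of |qx| = 4/48
        near = np.abs(np.abs(qx)[None, None, :] - 4 / 48) <= 1.5 / 48
        frac = spec[np.broadcast_to(near, spec.shape)].sum() / spec.sum()
        assert frac > 0.95

    def test_centro_symmetric_for_real_input(self, rng):
        w = kb_window(16, 6.0)
        spec = windowed_power_spectrum(rng.normal(size=(16, 16, 16)), w)
        flipped = spec[::-1, ::-1, ::-1]
        flipped = np.roll(flipped, 1, axis=(0, 1, 2))  # I(q) = I(-q)
        np.testing.assert_allclose(spec, flipped, rtol=1e-8, atol=1e-8)

    def test_dc_bin_zeroed(self, rng):
        w = kb_window(16, 6.0)
        spec = windowed_power_spectrum(rng.normal(size=(16, 16, 16)) + 5.0, w)
        assert spec[0, 0, 0] == 0.0

    def test_wrong_cube_size_rejected(self):
        with pytest.raises(ValueError):
            windowed_power_spectrum(np.zeros((8, 8, 8)), kb_window(16, 8.0))


def brute_force_covariance(spectrum, q_min, q_max):
    """Triple-loop oracle for the intensity-weighted frequency moments."""
    n = spectrum.shape[0]
    freqs = np.fft.fftfreq(n)
    C = np.zeros((3, 3))
    total = 0.0
    for iz in range(n):
        for iy in range(n):
            for ix in range(n):
                q = np.array([freqs[ix], freqs[iy], freqs[iz]])  # (x, y, z)
                r = np.sqrt(q @ q)
                if q_min <= r <= q_max:
                    w = spectrum[iz, iy, ix]
                    C += w * np.outer(q, q)
                    total += w
    return C / total, total


class TestSpectralCovariance:
    def test_matches_brute_force_oracle(self, rng):
        w = kb_window(16, 8.0)
        spec = windowed_power_spectrum(rng.normal(size=(16, 16, 16)), w)
        cov = spectral_covariance(spec, 0.05, 0.45)
        C_oracle, total_oracle = brute_force_covariance(spec, 0.05, 0.45)
        np.testing.assert_allclose(cov.C, C_oracle, rtol=1e-10)
        assert cov.total_weight == pytest.approx(total_oracle, rel=1e-10)

    def test_spherically_symmetric_spectrum_is_isotropic(self):
        n = 32
        qz, qy, qx = np.meshgrid(*[np.fft.fftfreq(n)] * 3, indexing="ij")
        spec = np.exp(-((qx**2 + qy**2 + qz**2) / 0.02))
        spec[0, 0, 0] = 0
        cov = spectral_covariance(spec, 0.02, 0.45)
        off = cov.C - np.diag(np.diag(cov.C))
        assert np.abs(off).max() < 1e-3 * np.trace(cov.C)
        assert np.allclose(np.diag(cov.C), np.trace(cov.C) / 3, rtol=0.01)

    def test_planar_spectrum_minor_axis_along_z(self):
        vol, gt = phantoms.fiber_phantom((32, 32, 32), "z", spacing=10,
                                         fiber_radius=2)
        w = kb_window(32, 8.0)
        spec = windowed_power_spectrum(vol.data, w)
        cov = spectral_covariance(spec, 0.05, 0.45)
        dec = eigendecompose(cov.C)
        assert axial_angle_deg(dec.eigenvectors[2], [0, 0, 1]) < 3.0

    def test_intensity_scaling_invariance(self, rng):
        w = kb_window(16, 8.0)
        spec = windowed_power_spectrum(rng.normal(size=(16, 16, 16)), w)
        c1 = spectral_covariance(spec, 0.05, 0.45)
        c2 = spectral_covariance(7.5 * spec, 0.05, 0.45)
        np.testing.assert_allclose(c1.C, c2.C, rtol=1e-12)

    def test_zero_weight_flagged_invalid(self):
        cov = spectral_covariance(np.zeros((8, 8, 8)), 0.05, 0.45)
        assert not cov.valid


class TestEigendecompose:
    def test_identity_is_fully_degenerate(self):
        dec = eigendecompose(np.eye(3))
        np.testing.assert_allclose(dec.eigenvalues, 1.0)
        assert dec.degenerate

    def test_diagonal_matrix(self):
        dec = eigendecompose(np.diag([3.0, 2.0, 1.0]))
        np.testing.assert_allclose(dec.eigenvalues, [3, 2, 1])
        np.testing.assert_allclose(np.abs(dec.eigenvectors), np.eye(3),
                                   atol=1e-12)
        assert not dec.degenerate

    def test_reconstruction_spectral_theorem(self, rng):
        A = rng.normal(size=(3, 3))
        C = A @ A.T  # random symmetric PSD
        dec = eigendecompose(C)
        recon = sum(lam * np.outer(v, v) for lam, v in
                    zip(dec.eigenvalues, dec.eigenvectors))
        assert np.linalg.norm(recon - C) < 1e-10 * np.linalg.norm(C)

    def test_right_handed_basis(self, rng):
        A = rng.normal(size=(3, 3))
        dec = eigendecompose(A @ A.T)
        assert np.linalg.det(dec.eigenvectors) == pytest.approx(1.0, abs=1e-10)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1, 2, 0], [0, 1, 0], [0, 0, 1.0]]))


class TestAnisotropyMeasures:
    @pytest.mark.parametrize("c", [1.0, 0.1, 42.0])
    def test_fa_zero_for_sphere(self, c):
        assert anisotropy_fa(c, c, c) == 0.0

    def test_fa_one_for_rod(self):
        assert anisotropy_fa(1.0, 0.0, 0.0) == 1.0

    def test_fa_midpoint_value(self):
        assert anisotropy_fa(2, 1, 1) == pytest.approx(np.sqrt(1 / 6))

    def test_fa_squared_is_square_of_fa(self):
        for triple in [(2, 1, 1), (5, 3, 1), (1, 1, 1)]:
            assert fa_squared(*triple) == pytest.approx(
                anisotropy_fa(*triple) ** 2, abs=1e-12)

    def test_reciprocal_sphere_limit(self):
        assert reciprocal_anisotropy(1, 1, 1) == 0.0

    def test_reciprocal_disk_limit(self):
        assert reciprocal_anisotropy(1, 1, 1e-6) == pytest.approx(1.0,
                                                                  abs=1e-3)

    def test_reciprocal_rod_limit(self):
        assert reciprocal_anisotropy(1e6, 1, 1) == pytest.approx(0.5,
                                                                 abs=1e-3)

    def test_reciprocal_zero_eigenvalue_is_nan(self):
        assert np.isnan(reciprocal_anisotropy(1, 1, 0))

    def test_sqrt_variant_differs_in_rod_limit(self):
        assert reciprocal_anisotropy(1e6, 1, 1, form="sqrt") == pytest.approx(
            np.sqrt(0.5), abs=1e-3)

    @given(st.tuples(st.floats(0.1, 100), st.floats(0.1, 100),
                     st.floats(0.1, 100)),
           st.floats(0.01, 50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounds_and_scale_invariance(self, triple, scale):
        om = anisotropy_fa(*triple)
        Om = reciprocal_anisotropy(*triple)
        assert 0.0 <= om <= 1.0 + 1e-12
        assert 0.0 <= Om <= 1.0 + 1e-12
        scaled = tuple(scale * t for t in triple)
        assert anisotropy_fa(*scaled) == pytest.approx(om, abs=1e-9)
        assert reciprocal_anisotropy(*scaled) == pytest.approx(Om, abs=1e-9)


class TestFiberOrientation:
    def _orientation_of(self, vol):
        w = kb_window(vol.shape[0], 8.0)
        spec = windowed_power_spectrum(vol.data, w)
        cov = spectral_covariance(spec, 0.05, 0.45)
        return fiber_orientation(eigendecompose(cov.C))

    def test_fibers_along_z(self):
        vol, gt = phantoms.fiber_phantom((48, 48, 48), "z", spacing=14,
                                         fiber_radius=3)
        res = self._orientation_of(vol)
        assert res.valid
        assert axial_angle_deg(res.vector, gt) < 3.0

    def test_fibers_along_diagonal(self):
        d = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        vol, gt = phantoms.fiber_phantom((48, 48, 48), d, spacing=14,
                                         fiber_radius=3)
        res = self._orientation_of(vol)
        assert res.valid
        assert axial_angle_deg(res.vector, gt) < 5.0

    def test_isotropic_noise_invalid(self, rng):
        vol = Volume3D(rng.normal(size=(48, 48, 48)), 1.0)
        res = self._orientation_of(vol)
        assert not res.valid

    def test_canonical_axial_representative(self):
        np.testing.assert_allclose(canonical_axial([0, 0, -1.0]), [0, 0, 1])
        np.testing.assert_allclose(canonical_axial([0, -1.0, 0]), [0, 1, 0])
        np.testing.assert_allclose(canonical_axial([-1.0, 0, 0]), [1, 0, 0])
        v = np.array([0.3, -0.4, -0.5])
        np.testing.assert_allclose(canonical_axial(v), -v)


class TestShellCurves:
    def test_white_noise_profile_is_flat(self, rng):
        l = 48
        w = kb_window(l, 8.0)
        spec = windowed_power_spectrum(rng.normal(size=(l, l, l)), w)
        q, prof = radial_profile(spec, 1 / l, q_max=0.5)
        mid = prof[(q > 0.1) & (q < 0.4)]
        assert np.std(mid) / np.mean(mid) < 0.2

    def test_lamellar_peak_shell(self):
        vol = phantoms.lamellar_phantom((48, 48, 48), 10.0, "x")
        w = kb_window(48, 8.0)
        spec = windowed_power_spectrum(vol.data, w)
        sw = 1 / 48
        q, prof = radial_profile(spec, sw, q_max=0.5)
        assert q[np.nanargmax(prof)] == pytest.approx(0.1, abs=sw)

    def test_zero_spectrum_zero_profile(self):
        q, prof = radial_profile(np.zeros((16, 16, 16)), 1 / 16)
        assert np.nansum(prof) == 0.0

    def test_invalid_shell_width_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(np.zeros((8, 8, 8)), 0.0)

    def test_isotropic_cone_equals_radial_profile(self, rng):
        n = 32
        qz, qy, qx = np.meshgrid(*[np.fft.fftfreq(n)] * 3, indexing="ij")
        spec = np.exp(-((qx**2 + qy**2 + qz**2) / 0.05))
        spec[0, 0, 0] = 0
        q, prof = radial_profile(spec, 1 / n, q_max=0.5)
        _, cone = cone_background(spec, [0, 0, 1], 30.0, 1 / n, q_max=0.5)
        sel = (q > 0.08) & (q < 0.4)
        np.testing.assert_allclose(cone[sel], prof[sel], rtol=0.05)

    def test_cone_along_fiber_axis_has_no_peak(self):
        # lamellae normal to x; the "fiber" direction is in the y-z plane
        vol = phantoms.lamellar_phantom((48, 48, 48), 10.0, "x")
        w = kb_window(48, 8.0)
        spec = windowed_power_spectrum(vol.data, w)
        q, bg = cone_background(spec, [0, 0, 1], 15.0, 1 / 48, q_max=0.5)
        _, sig = radial_profile(spec, 1 / 48, q_max=0.5)
        sel = (q > 0.06) & (q < 0.15)
        # the grating peak dominates the full shell average but must not
        # leak into the cone along the fiber direction
        assert np.nanmax(bg[sel]) < 1e-6 * np.nanmax(sig[sel])

    def test_full_sphere_cone_equals_radial_profile(self, rng):
        w = kb_window(16, 6.0)
        spec = windowed_power_spectrum(rng.normal(size=(16, 16, 16)), w)
        q, prof = radial_profile(spec, 1 / 16, q_max=0.5)
        _, cone = cone_background(spec, [0, 0, 1], 90.0, 1 / 16, q_max=0.5)
        np.testing.assert_allclose(cone, prof, rtol=1e-10, equal_nan=True)


class TestFiberDistance:
    def _distance(self, period, voxel_size, shape=(96, 96, 96)):
        vol = phantoms.lamellar_phantom(shape, period, "x",
                                        voxel_size=voxel_size)
        l = shape[0]
        w = kb_window(l, 8.0)
        spec = windowed_power_spectrum(vol.data, w)
        cov = spectral_covariance(spec, 0.02, 0.45)
        res = fiber_orientation(eigendecompose(cov.C))
        sw = 1 / l
        q, sig = radial_profile(spec, sw, q_max=0.45)
        _, bg = cone_background(spec, res.vector, 15.0, sw, q_max=0.45)
        return fiber_distance(q, sig, bg, (0.02, 0.45), voxel_size), sw

    def test_worked_correspondence_period14_at_5p3_um(self):
        peak, sw = self._distance(14.0, 5.3)
        assert peak is not None
        # 0.071 cycles/pixel -> 14 px -> 74.2 um
        assert peak.q_peak == pytest.approx(1 / 14, abs=sw)
        d_tol = 5.3 * sw / (1 / 14) ** 2  # one shell width, in um
        assert peak.distance_um == pytest.approx(74.2, abs=d_tol)

    def test_period10_at_unit_voxel(self):
        peak, sw = self._distance(10.0, 1.0)
        assert peak is not None
        assert peak.distance_um == pytest.approx(10.0,
                                                 abs=sw / (1 / 10) ** 2)

    def test_constant_volume_has_no_peak(self):
        q = np.linspace(0.01, 0.45, 40)
        sig = np.zeros_like(q)
        bg = np.zeros_like(q)
        assert fiber_distance(q, sig, bg, (0.02, 0.45), 1.0) is None

    def test_flat_ratio_rejected_by_threshold(self, rng):
        q = np.linspace(0.01, 0.45, 40)
        base = np.exp(-q * 3)
        assert fiber_distance(q, base, base, (0.02, 0.45), 1.0) is None


class TestAnalyzeVolume:
    def test_median_orientation_error_below_5deg(self, fiber_vol_z,
                                                 small_config):
        vol, gt = fiber_vol_z
        field = analyze_volume(vol, small_config)
        assert field.valid.sum() > 0
        dots = np.abs(field.orientation[field.valid] @ gt)
        errs = np.degrees(np.arccos(np.clip(dots, -1, 1)))
        assert np.median(errs) < 5.0

    def test_rotation_equivariance_90deg(self, small_config):
        vol, _ = phantoms.fiber_phantom((64, 64, 64), (1, 0, 1), spacing=14,
                                        fiber_radius=3)
        field = analyze_volume(vol, small_config, compute_distance=False)
        # rotate 90 deg in the x-z plane: (x, y, z) -> (-z, y, x)
        rot_data = np.rot90(vol.data, k=1, axes=(0, 2))
        rot_field = analyze_volume(vol.with_data(rot_data), small_config,
                                   compute_distance=False)
        R = np.array([[0, 0, -1], [0, 1, 0], [1, 0, 0]], float)
        assert field.valid.sum() > 0 and rot_field.valid.sum() > 0
        for vec in field.orientation[field.valid]:
            assert axial_angle_deg(vec, [1, 0, 1] / np.sqrt(2)) < 3.0
        expected = R @ ([1, 0, 1] / np.sqrt(2))
        for vec in rot_field.orientation[rot_field.valid]:
            assert axial_angle_deg(vec, expected) < 3.0

    def test_all_air_volume_has_no_valid_windows(self, small_config):
        vol = Volume3D(np.zeros((48, 48, 48)), 1.0)
        field = analyze_volume(vol, small_config)
        assert field.valid.sum() == 0

    def test_volume_smaller_than_window_rejected(self, small_config):
        vol = Volume3D(np.zeros((16, 16, 16)), 1.0)
        with pytest.raises(ValueError, match="smaller"):
            analyze_volume(vol, small_config)

    def test_orientation_invariant_to_intensity_offset(self, fiber_vol_z,
                                                       small_config):
        vol, _ = fiber_vol_z
        f1 = analyze_volume(vol, small_config, compute_distance=False)
        cfg = AnalysisConfig(**{**small_config.__dict__,
                                "tissue_threshold":
                                    small_config.tissue_threshold + 10.0})
        f2 = analyze_volume(vol.with_data(vol.data + 10.0), cfg,
                            compute_distance=False)
        both = f1.valid & f2.valid
        assert both.sum() > 0
        dots = np.abs(np.sum(f1.orientation[both] * f2.orientation[both],
                             axis=-1))
        assert np.degrees(np.arccos(np.clip(dots, -1, 1))).max() < 0.5

    def test_deterministic(self, fiber_vol_z, small_config):
        vol, _ = fiber_vol_z
        f1 = analyze_volume(vol, small_config)
        f2 = analyze_volume(vol, small_config)
        np.testing.assert_array_equal(f1.orientation, f2.orientation)
        np.testing.assert_array_equal(f1.distance_um, f2.distance_um)
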