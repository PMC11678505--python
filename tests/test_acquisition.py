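import numpy as np
import pytest

from petrr.acquisition import (
    AcquisitionError,
    AcquisitionSpec,
    add_poisson_noise,
    apply_psf,
    calibrate_fwhm,
    calibrate_post_filter,
    forward_project,
    fwhm_to_sigma,
    measure_point_source_fwhm,
    reconstruct_fbp,
    simulate_fbp,
)
from petrr.volumes import VoxelVolume

SP = (2.5, 2.5, 2.5)


def disk_volume(value=1.0, radius_mm=30.0, n=65):
    coords = (np.arange(n) - (n - 1) / 2) * SP[0]
    x, y = np.meshgrid(coords, coords, indexing="ij")
    data = np.zeros((n, n, 4))
    data[(x**2 + y**2 <= radius_mm**2)] = value
    return VoxelVolume(data, SP, "DP")


class TestApplyPsf:
    def test_sigma_closed_form(self):
        assert fwhm_to_sigma(8.0) == pytest.approx(3.3972, abs=1e-4)

    def test_zero_fwhm_is_identity(self, rng):
        vol = VoxelVolume(rng.random((8, 8, 8)), SP, "DP")
        out = apply_psf(vol, 0.0)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(AcquisitionError):
            apply_psf(VoxelVolume(np.zeros((4, 4, 4)), SP, "DP"), -1.0)

    def test_point_source_profile_fwhm(self):
        data = np.zeros((64, 64, 64))
        data[32, 32, 32] = 1.0
        out = apply_psf(VoxelVolume(data, SP, "DP"), 8.0)
        measured = measure_point_source_fwhm(out.data[:, :, 32], SP[0])
        assert 7.6 <= measured <= 8.4

    def test_flux_conserved_for_interior_support(self, default_phantom):
        dp = default_phantom.dp
        out = apply_psf(dp, 6.0)
        assert abs(out.data.sum() / dp.data.sum() - 1.0) < 0.005


class TestForwardProject:
    def test_linearity(self, rng):
        spec = AcquisitionSpec(n_angles=30)
        a = VoxelVolume(rng.random((16, 16, 2)), SP, "DP")
        b = VoxelVolume(rng.random((16, 16, 2)), SP, "DP")
        ab = VoxelVolume(a.data + b.data, SP, "DP")
        np.testing.assert_allclose(
            forward_project(ab, spec).data,
            forward_project(a, spec).data + forward_project(b, spec).data,
            atol=1e-9,
        )

    def test_zero_volume_projects_to_zero(self):
        spec = AcquisitionSpec(n_angles=12)
        sino = forward_project(VoxelVolume(np.zeros((16, 16, 2)), SP, "DP"), spec)
        assert np.all(sino.data == 0)

    def test_uniform_disk_central_chord(self):
        # central bin of a uniform disk = chord length x intensity = 2 R c
        c, radius = 1.7, 30.0
        spec = AcquisitionSpec(n_angles=8)
        sino = forward_project(disk_volume(c, radius), spec)
        centre_bin = sino.data.shape[1] // 2
        expected = 2 * radius * c
        got = sino.data[0, centre_bin, :]
        np.testing.assert_allclose(got, expected, rtol=0.05)


def test_sinogram_round_trip(tmp_path):
    from petrr.acquisition import read_sinogram, write_sinogram

    spec = AcquisitionSpec(n_angles=24)
    sino = forward_project(disk_volume(), spec)
    write_sinogram(sino, tmp_path / "sino.nii.gz")
    back = read_sinogram(tmp_path / "sino.nii.gz")
    np.testing.assert_allclose(back.data, sino.data, rtol=1e-6)
    np.testing.assert_allclose(back.angles_deg, sino.angles_deg)
    assert back.image_shape == sino.image_shape


class TestPoissonNoise:
    def test_expectation_preserved(self, rng):
        spec = AcquisitionSpec(n_angles=24, necr_random=False)
        sino = forward_project(disk_volume(), spec)
        noisy = [
            add_poisson_noise(sino, spec, rng=rng).data for _ in range(60)
        ]
        mean = np.mean(noisy, axis=0)
        # expectation preserved within Monte-Carlo tolerance on the total
        assert mean.sum() == pytest.approx(sino.data.sum(), rel=0.01)

    def test_high_count_limit_recovers_input(self, rng):
        spec = AcquisitionSpec(n_angles=24, necr_random=False, counts_per_kcps=1e6)
        sino = forward_project(disk_volume(), spec)
        noisy = add_poisson_noise(sino, spec, rng=rng)
        rel = np.linalg.norm(noisy.data - sino.data) / np.linalg.norm(sino.data)
        assert rel < 0.01

    def test_seeded_reproducibility(self):
        spec = AcquisitionSpec(n_angles=24, seed=5)
        sino = forward_project(disk_volume(), spec)
        a = add_poisson_noise(sino, spec)
        b = add_poisson_noise(sino, spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_sinogram_warns_and_returns_zero(self):
        spec = AcquisitionSpec(n_angles=12)
        sino = forward_project(VoxelVolume(np.zeros((16, 16, 1)), SP, "DP"), spec)
        with pytest.warns(RuntimeWarning):
            out = add_poisson_noise(sino, spec)
        assert np.all(out.data == 0)

    def test_necr_draws_positive_and_centred(self):
        spec = AcquisitionSpec()
        rng = np.random.default_rng(0)
        draws = np.array([spec.draw_necr(rng) for _ in range(500)])
        assert draws.min() > 0
        assert abs(draws.mean() - 75.0) < 26.0 / np.sqrt(500) * 5 + 1.0


class TestReconstruction:
    def test_round_trip_on_smooth_phantom(self, default_phantom):
        spec = AcquisitionSpec(n_angles=180)
        smooth = apply_psf(default_phantom.dp, 6.0)
        recon = reconstruct_fbp(forward_project(smooth, spec), spec)
        mask = default_phantom.labels.brain_mask()
        err = np.linalg.norm(recon.data[mask] - smooth.data[mask])
        err /= np.linalg.norm(smooth.data[mask])
        assert err < 0.05

    def test_zero_sinogram_reconstructs_zero(self):
        spec = AcquisitionSpec(n_angles=12)
        sino = forward_project(VoxelVolume(np.zeros((16, 16, 1)), SP, "DP"), spec)
        assert np.all(reconstruct_fbp(sino, spec).data == 0)

    def test_rotational_symmetry_preserved(self):
        spec = AcquisitionSpec(n_angles=90)
        recon = reconstruct_fbp(forward_project(disk_volume(), spec), spec)
        sl = recon.data[:, :, 0]
        assert np.abs(sl - sl.T).max() < 0.05 * sl.max()
        assert np.abs(sl - sl[::-1, ::-1]).max() < 0.05 * sl.max()

    def test_noise_decreases_with_counts(self, default_phantom):
        smooth = apply_psf(default_phantom.dp, 6.0)
        rms = []
        for scale in (0.03, 1.0, 30.0):
            spec = AcquisitionSpec(n_angles=60, necr_random=False,
                                   counts_per_kcps=scale, seed=3)
            sino = add_poisson_noise(forward_project(smooth, spec), spec)
            recon = reconstruct_fbp(sino, spec)
            rms.append(np.sqrt(np.mean((recon.data - smooth.data) ** 2)))
        assert rms[0] > rms[1] > rms[2]


class TestCalibration:
    def test_psf_only_chain_measures_the_psf(self):
        spec = AcquisitionSpec(pre_filter_fwhm_mm=8.0)
        measured = calibrate_fwhm(spec, SP, (64, 64, 8), post_filter_fwhm_mm=0.0,
                                  include_projection=False)
        assert 7.6 <= measured <= 8.4

    def test_post_filter_monotone(self):
        spec = AcquisitionSpec(n_angles=60)
        shape = (64, 64, 4)
        lo = calibrate_fwhm(spec, SP, shape, post_filter_fwhm_mm=1.0)
        hi = calibrate_fwhm(spec, SP, shape, post_filter_fwhm_mm=6.0)
        assert hi > lo

    def test_calibrated_chain_hits_target(self):
        spec = AcquisitionSpec(n_angles=120)
        post = calibrate_post_filter(spec, SP, (64, 64, 8))
        measured = calibrate_fwhm(spec, SP, (64, 64, 8), post_filter_fwhm_mm=post)
        assert 7.2 <= measured <= 8.8


class TestSimulateFbp:
    def test_deterministic_given_seed(self, midburden_phantom):
        spec = AcquisitionSpec(n_angles=60, seed=9, post_filter_fwhm_mm=4.5)
        a = simulate_fbp(midburden_phantom.dp, spec)
        b = simulate_fbp(midburden_phantom.dp, spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_output_nonnegative_simfbp(self, midburden_phantom):
        spec = AcquisitionSpec(n_angles=60, seed=1, post_filter_fwhm_mm=4.5)
        out = simulate_fbp(midburden_phantom.dp, spec)
        assert out.modality == "SIMFBP"
        assert out.data.min() >= 0
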