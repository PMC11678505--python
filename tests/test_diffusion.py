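import numpy as np
import pytest

from petrr.diffusion import (
    DiffusionBatch,
    DiffusionConfig,
    DiffusionError,
    LossWeights,
    estimate_z0,
    gamma_t,
    loss_combined,
    loss_image,
    loss_noise,
    make_schedule,
    ms_ssim,
    predict_noise,
    q_sample,
    sample,
    train_ldm,
    LDMState,
    UNet,
)
from petrr.nn.autograd import Tensor


@pytest.fixture(scope="module")
def schedule():
    return make_schedule(200)


def latent_triples(n=10, shape=(3, 8, 8, 8), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        z = rng.standard_normal(shape)
        out.append((z, z * 0.5 + rng.standard_normal(shape) * 0.1,
                    z * 0.8 + rng.standard_normal(shape) * 0.1))
    return out


class TestSchedule:
    def test_default_settings_decay_below_threshold(self):
        sch = make_schedule()  # T=1000, linear 1e-4 -> 0.02
        assert sch.T == 1000
        assert sch.alpha_bar[-1] < 1e-4
        assert np.all(np.diff(sch.alpha_bar) < 0)
        assert np.all((sch.beta > 0) & (sch.beta < 1))
        assert np.all(sch.posterior_var >= 0)
        assert sch.posterior_var[0] == 0.0  # alpha_bar_0 == 1 convention

    def test_single_step_schedule(self):
        sch = make_schedule(1, 0.5, 0.5)
        assert sch.alpha_bar[0] == pytest.approx(0.5)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(DiffusionError):
            make_schedule(10, 0.2, 0.1)
        with pytest.raises(DiffusionError):
            make_schedule(0)


class TestForwardAlgebra:
    def test_q_sample_closed_form_value(self, schedule):
        # pick the timestep whose cumulative signal fraction is nearest 0.25
        t = int(np.argmin(np.abs(schedule.alpha_bar - 0.25))) + 1
        ab = schedule.alpha_bar[t - 1]
        z = q_sample(np.array(1.0), t, np.array(2.0), schedule)
        assert z == pytest.approx(np.sqrt(ab) + 2 * np.sqrt(1 - ab))

    def test_zero_noise_branch(self, schedule):
        z0 = np.full((2, 2, 2), 1.5)
        zt = q_sample(z0, 50, np.zeros_like(z0), schedule)
        np.testing.assert_allclose(zt, np.sqrt(schedule.alpha_bar[49]) * z0)

    def test_inversion_identity_all_timesteps(self, schedule, rng):
        z0 = rng.standard_normal((3, 8, 8, 8))
        for t in range(1, schedule.T + 1):
            eps = rng.standard_normal(z0.shape)
            back = estimate_z0(q_sample(z0, t, eps, schedule), t, eps, schedule)
            assert np.abs(back - z0).max() < 1e-10

    def test_zero_predicted_noise(self, schedule):
        zt = np.ones((2, 2, 2))
        z0h = estimate_z0(zt, 100, np.zeros_like(zt), schedule)
        np.testing.assert_allclose(z0h, zt / np.sqrt(schedule.alpha_bar[99]))

    def test_forward_marginal_moments(self, schedule, rng):
        t, z0 = 120, 0.7
        draws = q_sample(
            np.full(10_000, z0), t, rng.standard_normal(10_000), schedule
        )
        ab = schedule.alpha_bar[t - 1]
        se_mean = np.sqrt(1 - ab) / 100
        assert abs(draws.mean() - np.sqrt(ab) * z0) < 4 * se_mean
        assert abs(draws.var() - (1 - ab)) < 4 * (1 - ab) * np.sqrt(2 / 10_000)

    def test_out_of_range_timestep(self, schedule):
        with pytest.raises(DiffusionError):
            q_sample(np.zeros(2), 0, np.zeros(2), schedule)
        with pytest.raises(DiffusionError):
            q_sample(np.zeros(2), 201, np.zeros(2), schedule)

    def test_gamma_identity(self, schedule, rng):
        # image-scale L2 == gamma_t * noise-scale L2, at timesteps spanning
        # the schedule including ones with alpha_bar near 0.5 and 0.25
        z0 = rng.standard_normal((3, 8, 8, 8))
        ts = np.unique(np.linspace(1, schedule.T, 10).astype(int))
        ts = np.append(ts, [int(np.argmin(np.abs(schedule.alpha_bar - a))) + 1
                            for a in (0.5, 0.25)])
        for t in ts:
            eps = rng.standard_normal(z0.shape)
            eps_hat = rng.standard_normal(z0.shape)
            zt = q_sample(z0, int(t), eps, schedule)
            z0_hat = estimate_z0(zt, int(t), eps_hat, schedule)
            lhs = np.mean((z0 - z0_hat) ** 2)
            rhs = gamma_t(schedule, int(t)) * np.mean((eps - eps_hat) ** 2)
            assert abs(lhs / rhs - 1) < 1e-8


class TestMsSsim:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((8, 8, 8))
        assert ms_ssim(x, x) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        assert ms_ssim(a, b) == pytest.approx(ms_ssim(b, a))

    def test_constant_images_closed_form(self):
        c1, c2, L = 1.0, 2.0, 2.0
        a = np.full((8, 8, 8), c1)
        b = np.full((8, 8, 8), c2)
        C1 = (0.01 * L) ** 2
        expected = (2 * c1 * c2 + C1) / (c1**2 + c2**2 + C1)
        got = ms_ssim(a, b, n_scales=1, window=3, data_range=L)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_single_scale_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.random((10, 10, 10))
        b = np.clip(a + 0.2 * rng.standard_normal(a.shape), 0, 1)
        mine = ms_ssim(a, b, n_scales=1, window=7, data_range=1.0)
        theirs = structural_similarity(
            a, b, win_size=7, data_range=1.0, use_sample_covariance=False,
            gaussian_weights=False,
        )
        # same statistic up to map-edge (valid-window) handling
        assert mine == pytest.approx(theirs, abs=0.02)

    def test_too_small_input_raises_with_guidance(self):
        with pytest.raises(DiffusionError, match="reduce"):
            ms_ssim(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), n_scales=2, window=3)

    def test_less_similar_scores_lower(self, rng):
        a = rng.random((8, 8, 8))
        near = a + 0.05 * rng.standard_normal(a.shape)
        far = rng.random((8, 8, 8))
        assert ms_ssim(a, near) > ms_ssim(a, far)


class TestLosses:
    def test_noise_loss_values(self):
        assert loss_noise(np.array([0.0, 0.0]), np.array([1.0, -1.0])) == 1.0
        assert loss_noise(np.ones(4), np.ones(4)) == 0.0

    def test_noise_loss_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = rng.standard_normal((3, 16))
            assert loss_noise(a, c) <= loss_noise(a, b) + loss_noise(b, c) + 1e-12

    def test_image_loss_zero_iff_perfect(self, rng):
        z = rng.random((3, 8, 8, 8))
        assert loss_image(z, z) == pytest.approx(0.0, abs=1e-12)
        assert loss_image(z, z + 0.1) > 0

    def test_alpha_zero_reduces_to_mse(self, rng):
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        got = loss_image(a, b, LossWeights(alpha_ms=0.0))
        assert got == pytest.approx(np.mean((a - b) ** 2), rel=1e-12)

    def test_combined_loss_zero_for_perfect_prediction(self, schedule, rng):
        z0 = rng.standard_normal((1, 3, 8, 8, 8))
        eps = rng.standard_normal(z0.shape)
        batch = DiffusionBatch(z0=z0, t=np.array([40]), eps=eps, eps_hat=eps)
        assert loss_combined(batch, schedule) == pytest.approx(0.0, abs=1e-9)

    def test_combined_loss_positive_otherwise(self, schedule, rng):
        z0 = rng.standard_normal((1, 3, 8, 8, 8))
        eps = rng.standard_normal(z0.shape)
        batch = DiffusionBatch(z0=z0, t=np.array([40]), eps=eps,
                               eps_hat=eps + 0.3)
        assert loss_combined(batch, schedule) > 0


class TestUNet:
    def test_predict_noise_contracts(self, schedule, rng):
        cfg = DiffusionConfig(width=8, seed=1)
        unet = UNet(3, 6, width=8, seed=1)
        state = LDMState(unet, cfg, schedule=schedule)
        zt = rng.standard_normal((3, 8, 8, 8)).astype(np.float32)
        cond = (rng.standard_normal((3, 8, 8, 8)), rng.standard_normal((3, 8, 8, 8)))
        out = predict_noise(zt, 10, cond, state)
        assert out.shape == zt.shape
        np.testing.assert_array_equal(out, predict_noise(zt, 10, cond, state))

    def test_missing_conditioning_rejected(self, schedule):
        state = LDMState(UNet(3, 6, width=8), DiffusionConfig(), schedule=schedule)
        with pytest.raises(DiffusionError):
            predict_noise(np.zeros((3, 8, 8, 8)), 5, None, state)
        with pytest.raises(DiffusionError):
            predict_noise(np.zeros((3, 8, 8, 8)), 5,
                          (np.zeros((3, 8, 8, 8)), np.zeros((3, 4, 4, 4))), state)

    def test_batch_order_equivariance(self, schedule, rng):
        state = LDMState(UNet(3, 6, width=8, seed=2), DiffusionConfig(),
                         schedule=schedule)
        zt = rng.standard_normal((4, 3, 8, 8, 8)).astype(np.float32)
        cond = (rng.standard_normal((4, 3, 8, 8, 8)).astype(np.float32),
                rng.standard_normal((4, 3, 8, 8, 8)).astype(np.float32))
        out = predict_noise(zt, 17, cond, state)
        perm = np.array([2, 0, 3, 1])
        out_p = predict_noise(zt[perm], 17, (cond[0][perm], cond[1][perm]), state)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-6)


class TestTraining:
    def test_loss_decreases_and_aes_frozen(self, schedule):
        from petrr.autoencoder import AutoencoderConfig, train_autoencoder

        ae_cfg = AutoencoderConfig(sub_volume_shape=(16, 16, 16), width=8,
                                   latent_channels=2, epochs=1, seed=0)
        ae = train_autoencoder([np.random.default_rng(0).random((16, 16, 16))
                                for _ in range(4)], ae_cfg, "DP")
        before = [a.copy() for a in ae.model.state_arrays()]
        triples = latent_triples(12, shape=(3, 8, 8, 8))
        state = train_ldm(triples, schedule, LossWeights(),
                          DiffusionConfig(width=8, steps=60, batch_size=4, seed=3),
                          ae_states={"DP": ae})
        h = state.loss_history
        assert np.mean(h[-20:]) < np.mean(h[:20])
        for a, b in zip(before, ae.model.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_seeded_training_reproducible(self, schedule):
        triples = latent_triples(6)
        cfg = DiffusionConfig(width=8, steps=10, batch_size=2, seed=9)
        a = train_ldm(triples, schedule, LossWeights(), cfg)
        b = train_ldm(triples, schedule, LossWeights(), cfg)
        assert a.loss_history == b.loss_history

    def test_combined_and_noise_space_modes_agree_at_alpha_zero(self, schedule):
        # the gamma identity makes the two objectives equal term by term
        triples = latent_triples(6)
        w = LossWeights(alpha_ms=0.0)
        a = train_ldm(triples, schedule, w,
                      DiffusionConfig(width=8, steps=8, batch_size=2, seed=5,
                                      loss_mode="combined"))
        b = train_ldm(triples, schedule, w,
                      DiffusionConfig(width=8, steps=8, batch_size=2, seed=5,
                                      loss_mode="noise_space"))
        np.testing.assert_allclose(a.loss_history, b.loss_history, rtol=1e-3)

    def test_empty_dataset_rejected(self, schedule):
        with pytest.raises(DiffusionError):
            train_ldm([], schedule)


@pytest.fixture(scope="module")
def trained(schedule):
    triples = latent_triples(16, seed=4)
    state = train_ldm(triples, schedule, LossWeights(),
                      DiffusionConfig(width=8, steps=150, batch_size=4, seed=2))
    return state, triples


class TestSampling:

    def test_reproducible_given_seed(self, schedule, trained):
        state, triples = trained
        cond = (triples[0][1].astype(np.float32), triples[0][2].astype(np.float32))
        a = sample(cond, schedule, state, n_steps=10, seed=7)
        b = sample(cond, schedule, state, n_steps=10, seed=7)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_ancestral_runs_and_is_finite(self, schedule, trained):
        state, triples = trained
        cond = (triples[0][1].astype(np.float32), triples[0][2].astype(np.float32))
        out = sample(cond, schedule, state, method="ancestral", seed=1)
        assert out.shape == triples[0][0].shape
        assert np.all(np.isfinite(out))

    def test_too_many_steps_rejected(self, schedule, trained):
        state, triples = trained
        cond = (triples[0][1].astype(np.float32), triples[0][2].astype(np.float32))
        with pytest.raises(DiffusionError):
            sample(cond, schedule, state, n_steps=schedule.T + 1)

    def test_strided_with_all_steps_visits_every_timestep(self, trained):
        # stride-1 degeneracy: n_steps == T covers 1..T exactly
        sch = make_schedule(25)
        ts = np.unique(np.linspace(1, sch.T, sch.T).round().astype(int))
        assert len(ts) == sch.T

    def test_checkpoint_round_trip_reproduces_samples(self, schedule, trained,
                                                      tmp_path):
        from petrr.diffusion import load_ldm, save_ldm

        state, triples = trained
        path = tmp_path / "ldm.npz"
        save_ldm(state, path)
        back = load_ldm(path)
        cond = (triples[0][1].astype(np.float32), triples[0][2].astype(np.float32))
        np.testing.assert_array_equal(
            sample(cond, schedule, state, n_steps=8, seed=2),
            sample(cond, back.schedule, back, n_steps=8, seed=2),
        )

    def test_oracle_noise_one_step_recovery(self, schedule, rng):
        # a sampler step with the true eps at t recovers z0 exactly
        z0 = rng.standard_normal((3, 8, 8, 8))
        eps = rng.standard_normal(z0.shape)
        zt = q_sample(z0, schedule.T, eps, schedule)
        z0_hat = estimate_z0(zt, schedule.T, eps, schedule)
        np.testing.assert_allclose(z0_hat, z0, atol=1e-9)
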