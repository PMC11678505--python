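"""Conditional latent diffusion for PET resolution recovery.

A DDPM-style diffusion model operates on the autoencoder latents of the
ground-truth digital phantom, conditioned on the latents of the matching MRI
and of the low-resolution scan (channel-wise concatenation at the U-Net
input).  The forward process adds Gaussian noise over ``T`` steps with a fixed
variance schedule ``beta_t``; writing ``alpha_t = 1 - beta_t`` and
``alpha_bar_t`` for the cumulative product, the closed-form forward marginal
and its inversion are

    z_t     = sqrt(alpha_bar_t) z_0 + sqrt(1 - alpha_bar_t) eps
    z_0_hat = (z_t - sqrt(1 - alpha_bar_t) eps_hat) / sqrt(alpha_bar_t)

The training objective is a combined noise-scale/image-scale loss

    L = L1(eps, eps_hat) + (1 - a) L2(z_0, z_0_hat) + a (1 - MS-SSIM(z_0, z_0_hat))

with ``a = 0.8``: the L1 term preserves voxel-level detail in the denoising
process, while the L2 and multi-scale structural-similarity terms act on the
estimated clean latent and preserve image-level structure.  Because the z_0
estimate is linear in eps_hat, the image-scale L2 term equals
``gamma_t * L2(eps, eps_hat)`` with ``gamma_t = (1 - alpha_bar_t)/alpha_bar_t``;
the implementation computes the image-scale form directly and uses the
identity as a test oracle (and as an optional equivalent noise-space training
mode).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autoencoder import (
    AutoencoderState,
    LatentBlock,
    decode,
    encode,
    tile_volume,
    untile_volume,
)
from .nn.autograd import Tensor, avg_pool3d, concat, conv3d, upsample3d
from .nn.layers import Conv3d, Linear, Module, sinusoidal_embedding
from .nn.optim import Adam, EmaWeights
from .volumes import VoxelVolume

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "LossWeights",
    "DiffusionBatch",
    "q_sample",
    "estimate_z0",
    "gamma_t",
    "ms_ssim",
    "loss_image",
    "loss_noise",
    "loss_combined",
    "UNet",
    "DiffusionConfig",
    "LDMState",
    "predict_noise",
    "train_ldm",
    "sample",
    "save_ldm",
    "load_ldm",
    "SuperResolveConfig",
    "super_resolve",
]


class DiffusionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# schedule and forward-process algebra


@dataclass(frozen=True)
class NoiseSchedule:
    """Fixed variance schedule and derived quantities.

    Arrays are indexed 0..T-1 for timesteps 1..T.  ``posterior_var[t-1]`` is
    sigma_t^2 = (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) * beta_t with the
    convention alpha_bar_0 = 1 (so sigma_1^2 = 0).
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    posterior_var: np.ndarray

    def check_t(self, t) -> np.ndarray:
        t = np.asarray(t)
        if np.any((t < 1) | (t > self.T)):
            raise DiffusionError(f"t must lie in [1, {self.T}]")
        return t


def make_schedule(
    T: int = 1000, beta_start: float = 1e-4, beta_end: float = 0.02,
    kind: str = "linear",
) -> NoiseSchedule:
    """Build a noise schedule; ``linear`` interpolates beta uniformly."""
    if not (0 < beta_start <= beta_end < 1):
        raise DiffusionError("need 0 < beta_start <= beta_end < 1")
    if T < 1:
        raise DiffusionError("T must be >= 1")
    if kind == "linear":
        beta = np.linspace(beta_start, beta_end, T)
    elif kind == "cosine":  # squared-cosine alpha_bar
        s = 0.008
        ts = np.arange(T + 1) / T
        ab = np.cos((ts + s) / (1 + s) * np.pi / 2) ** 2
        beta = np.clip(1 - ab[1:] / ab[:-1], beta_start, 0.999)
    else:
        raise DiffusionError(f"unknown schedule kind {kind!r}")
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    prev = np.concatenate([[1.0], alpha_bar[:-1]])
    posterior_var = (1.0 - prev) / (1.0 - alpha_bar) * beta
    return NoiseSchedule(T, beta, alpha, alpha_bar, posterior_var)


def _coeffs(schedule: NoiseSchedule, t, ndim: int):
    """sqrt(alpha_bar_t), sqrt(1 - alpha_bar_t), shaped to broadcast."""
    t = schedule.check_t(t)
    ab = schedule.alpha_bar[t - 1]
    if np.ndim(ab) > 0:
        shape = (len(np.atleast_1d(ab)),) + (1,) * (ndim - 1)
        ab = np.asarray(ab).reshape(shape)
    return np.sqrt(ab), np.sqrt(1.0 - ab)


def q_sample(z0, t, eps, schedule: NoiseSchedule):
    """Forward noising: z_t = sqrt(ab_t) z_0 + sqrt(1-ab_t) eps.

    Works on numpy arrays or autodiff tensors; ``t`` may be a scalar timestep
    or one per leading batch element.
    """
    ndim = z0.ndim if hasattr(z0, "ndim") else np.ndim(z0)
    a, b = _coeffs(schedule, t, ndim)
    return a * z0 + b * eps


def estimate_z0(zt, t, eps_hat, schedule: NoiseSchedule):
    """Invert the forward marginal: z_0_hat = (z_t - sqrt(1-ab_t) eps_hat)/sqrt(ab_t)."""
    ndim = zt.ndim if hasattr(zt, "ndim") else np.ndim(zt)
    a, b = _coeffs(schedule, t, ndim)
    return (zt - b * eps_hat) / a


def gamma_t(schedule: NoiseSchedule, t):
    """(1 - alpha_bar_t) / alpha_bar_t, the image/noise L2 conversion factor."""
    t = schedule.check_t(t)
    ab = schedule.alpha_bar[t - 1]
    return (1.0 - ab) / ab


# ---------------------------------------------------------------------------
# losses


@dataclass(frozen=True)
class LossWeights:
    """Mixing weights of the combined objective; ``alpha_ms`` is the MS-SSIM
    weight (0.8 by default) shared between the L2 and structure terms."""

    alpha_ms: float = 0.8
    ms_scales: int = 2
    ms_window: int = 3
    data_range: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_ms <= 1.0:
            raise DiffusionError("alpha_ms must lie in [0, 1]")


def _as_batched(x) -> Tensor:
    t = Tensor.as_tensor(x)
    if t.ndim == 3:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 4:
        t = t.reshape(1, *t.shape)
    elif t.ndim != 5:
        raise DiffusionError(f"expected 3D/4D/5D input, got {t.ndim}D")
    return t


def ms_ssim(a, b, n_scales: int = 2, window: int = 3, data_range: float = 1.0):
    """Multi-scale structural similarity over 3D windows.

    Contrast/structure terms are averaged at every scale and the luminance
    term enters at the coarsest scale; per-scale exponents are uniform (1/M).
    Symmetric in (a, b), equal to 1 iff a == b.  Accepts numpy arrays (returns
    a float) or autodiff tensors (returns a scalar tensor on the tape).
    Channels are treated independently.
    """
    numpy_in = not isinstance(a, Tensor) and not isinstance(b, Tensor)
    ta, tb = _as_batched(a), _as_batched(b)
    if ta.shape != tb.shape:
        raise DiffusionError("ms_ssim operands must share a shape")
    n, c, *spatial = ta.shape
    need = window * 2 ** (n_scales - 1)
    if min(spatial) < need:
        raise DiffusionError(
            f"spatial size {spatial} too small for window {window} at "
            f"{n_scales} scales (needs >= {need}); reduce n_scales or window"
        )
    # fold channels into the batch so each channel is scored independently
    ta = ta.reshape(n * c, 1, *spatial)
    tb = tb.reshape(n * c, 1, *spatial)
    kernel = Tensor(
        np.full((1, 1, window, window, window), 1.0 / window**3, dtype=ta.data.dtype)
    )
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2

    def blur(x):
        return conv3d(x, kernel, pad=0)

    terms = []
    for scale in range(n_scales):
        mu_a, mu_b = blur(ta), blur(tb)
        va = blur(ta * ta) - mu_a * mu_a
        vb = blur(tb * tb) - mu_b * mu_b
        cov = blur(ta * tb) - mu_a * mu_b
        cs = (2.0 * cov + c2) / (va + vb + c2)
        if scale == n_scales - 1:
            lum = (2.0 * mu_a * mu_b + c1) / (mu_a * mu_a + mu_b * mu_b + c1)
            terms.append((lum * cs).mean().clamp_min(1e-8))
        else:
            terms.append(cs.mean().clamp_min(1e-8))
            ta, tb = avg_pool3d(ta), avg_pool3d(tb)
    out = terms[0] ** (1.0 / n_scales)
    for term in terms[1:]:
        out = out * term ** (1.0 / n_scales)
    return float(out.data) if numpy_in else out


def loss_noise(eps, eps_hat):
    """Noise-scale L1: mean absolute error between drawn and predicted noise."""
    e, eh = Tensor.as_tensor(eps), Tensor.as_tensor(eps_hat)
    out = (e - eh).abs().mean()
    return float(out.data) if not isinstance(eps_hat, Tensor) and not isinstance(eps, Tensor) else out


def loss_image(z0, z0_hat, weights: LossWeights = LossWeights()):
    """Image-scale term: (1-a) L2 + a (1 - MS-SSIM), zero iff z0_hat == z0."""
    numpy_in = not isinstance(z0, Tensor) and not isinstance(z0_hat, Tensor)
    a, ah = Tensor.as_tensor(z0), Tensor.as_tensor(z0_hat)
    mse = ((a - ah) ** 2).mean()
    out = (1.0 - weights.alpha_ms) * mse
    if weights.alpha_ms > 0:
        sim = ms_ssim(a, ah, weights.ms_scales, weights.ms_window, weights.data_range)
        out = out + weights.alpha_ms * (1.0 - sim)
    return float(out.data) if numpy_in else out


@dataclass
class DiffusionBatch:
    """One training batch of the diffusion stage (latent-space tensors)."""

    z0: np.ndarray
    t: np.ndarray
    eps: np.ndarray
    zt: np.ndarray | None = None
    cond: tuple[np.ndarray, np.ndarray] | None = None
    eps_hat: np.ndarray | None = None
    z0_hat: np.ndarray | None = None


def loss_combined(batch: DiffusionBatch, schedule: NoiseSchedule,
                  weights: LossWeights = LossWeights()):
    """Noise-scale L1 plus the image-scale L2/MS-SSIM term."""
    if batch.eps_hat is None:
        raise DiffusionError("batch.eps_hat must be populated")
    z0_hat = batch.z0_hat
    if z0_hat is None:
        zt = batch.zt
        if zt is None:
            zt = q_sample(batch.z0, batch.t, batch.eps, schedule)
        z0_hat = estimate_z0(zt, batch.t, batch.eps_hat, schedule)
    return loss_noise(batch.eps, batch.eps_hat) + loss_image(batch.z0, z0_hat, weights)


# ---------------------------------------------------------------------------
# model


class UNet(Module):
    """Small 3D U-Net predicting the added noise from [z_t || z_MR || z_SP].

    One down/up level with a skip connection and additive timestep embeddings;
    sized for latent grids of ~8^3-16^3 voxels.

    ``parametrization`` selects what the output head represents: ``"eps"``
    (the added noise directly) or ``"x0"`` (the clean-latent estimate, from
    which eps_hat follows exactly via the forward-marginal identity
    eps_hat = (z_t - sqrt(ab_t) z0_hat)/sqrt(1 - ab_t)).  Both parametrize the
    same predicted-noise model and are trained with the same combined loss;
    the x0 head keeps the high-noise timesteps well-conditioned at small
    network sizes and is the default.
    """

    def __init__(self, latent_channels: int = 3, cond_channels: int = 6,
                 width: int = 32, temb_dim: int = 16, seed: int = 0,
                 parametrization: str = "x0"):
        if parametrization not in ("eps", "x0"):
            raise DiffusionError(f"unknown parametrization {parametrization!r}")
        self.parametrization = parametrization
        rng = np.random.default_rng(np.random.SeedSequence([seed, 503]))
        self.latent_channels = latent_channels
        self.cond_channels = cond_channels
        self.temb_dim = temb_dim
        self.temb1 = Linear(temb_dim, width, rng=rng)
        self.temb2 = Linear(temb_dim, width, rng=rng)
        self.in_conv = Conv3d(latent_channels + cond_channels, width, rng=rng)
        self.enc = Conv3d(width, width, rng=rng)
        self.mid = Conv3d(width, width, rng=rng)
        self.mid2 = Conv3d(width, width, rng=rng)
        self.dec = Conv3d(2 * width, width, rng=rng)
        self.out_conv = Conv3d(width, latent_channels, rng=rng)
        self.out_conv.weight.data *= 0.1  # near-zero initial prediction

    def forward(self, zt: Tensor, t, cond: Tensor) -> Tensor:
        n = zt.shape[0]
        emb = np.stack(
            [sinusoidal_embedding(int(ti), self.temb_dim) for ti in np.broadcast_to(t, (n,))]
        ).astype(zt.data.dtype)
        e1 = self.temb1(Tensor(emb)).reshape(n, -1, 1, 1, 1)
        e2 = self.temb2(Tensor(emb)).reshape(n, -1, 1, 1, 1)
        x = concat([zt, cond], axis=1)
        h1 = (self.in_conv(x) + e1).silu()
        h1 = self.enc(h1).silu()
        h2 = avg_pool3d(h1)
        h2 = (self.mid(h2) + e2).silu()
        h2 = self.mid2(h2).silu()
        h = concat([h1, upsample3d(h2)], axis=1)
        h = self.dec(h).silu()
        return self.out_conv(h)


@dataclass(frozen=True)
class DiffusionConfig:
    width: int = 32
    temb_dim: int = 16
    batch_size: int = 8
    steps: int = 600
    learning_rate: float = 2e-3
    lr_final_frac: float = 0.1  # exponential decay to this fraction over the run
    loss_mode: str = "combined"  # or "noise_space" (equivalent, see module doc)
    parametrization: str = "x0"  # output head; "eps" predicts the noise directly
    grad_clip_norm: float = 1.0  # 0 disables
    ema_decay: float = 0.995  # EMA weights installed after training; 0 disables
    seed: int = 0


@dataclass
class LDMState:
    """Trained diffusion stage: U-Net weights plus latent normalization."""

    unet: UNet
    config: DiffusionConfig
    latent_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    loss_history: list[float] = field(default_factory=list)
    schedule: NoiseSchedule | None = None
    #: range of the standardized training z0 values; samplers clamp the
    #: clean-latent estimate to it (static thresholding) so the decoder is
    #: never asked to extrapolate
    z0_range: tuple[float, float] | None = None

    def standardize(self, z: np.ndarray, modality: str) -> np.ndarray:
        m, s = self.latent_stats.get(modality, (0.0, 1.0))
        return (z - m) / s

    def destandardize(self, z: np.ndarray, modality: str) -> np.ndarray:
        m, s = self.latent_stats.get(modality, (0.0, 1.0))
        return z * s + m


def _model_predictions(unet: UNet, zt: Tensor, t, cond: Tensor,
                       schedule: NoiseSchedule) -> tuple[Tensor, Tensor]:
    """One forward pass -> (eps_hat, z0_hat), respecting the output head."""
    out = unet(zt, t, cond)
    a, b = _coeffs(schedule, t, 5)
    a = np.asarray(a, dtype=np.float32)
    b = np.asarray(b, dtype=np.float32)
    if unet.parametrization == "x0":
        z0_hat = out
        eps_hat = (zt - a * out) / b
    else:
        eps_hat = out
        z0_hat = (zt - b * out) / a
    return eps_hat, z0_hat


def predict_noise(zt, t, cond, state: LDMState, schedule: NoiseSchedule | None = None):
    """Predict eps from a noisy latent and its (z_MR, z_SP) conditioning.

    ``cond`` is the pair of conditioning latents (already standardized);
    numpy in, numpy out (no gradients recorded).
    """
    if cond is None or len(cond) != 2:
        raise DiffusionError("cond must be the (z_MR, z_SP) pair")
    schedule = schedule or state.schedule
    if schedule is None:
        raise DiffusionError("no noise schedule available")
    z_mr, z_sp = (np.asarray(c, dtype=np.float32) for c in cond)
    zt = np.asarray(zt, dtype=np.float32)
    batched = zt.ndim == 5
    if not batched:
        zt, z_mr, z_sp = zt[None], z_mr[None], z_sp[None]
    if z_mr.shape != zt.shape or z_sp.shape != zt.shape:
        raise DiffusionError("conditioning latents must match z_t's shape")
    eps_hat, _ = _model_predictions(
        state.unet, Tensor(zt), t, Tensor(np.concatenate([z_mr, z_sp], axis=1)),
        schedule,
    )
    return eps_hat.data if batched else eps_hat.data[0]


# ---------------------------------------------------------------------------
# training


def train_ldm(
    latent_triples: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    schedule: NoiseSchedule,
    weights: LossWeights = LossWeights(),
    config: DiffusionConfig = DiffusionConfig(),
    ae_states: dict[str, AutoencoderState] | None = None,
) -> LDMState:
    """Train the diffusion U-Net on (z0_DP, z_MR, z_SP) latent triples.

    Autoencoders are frozen: only U-Net parameters receive updates.  Latents
    are standardized per modality (scalar mean/SD over the dataset, stored in
    the returned state).  Each step draws per-sample uniform timesteps and
    Gaussian noise, forms z_t, predicts eps_hat and minimises the combined
    loss (or its equivalent noise-space form).
    """
    if not latent_triples:
        raise DiffusionError("empty latent dataset")
    ae_snapshot = None
    if ae_states:
        ae_snapshot = {
            k: [a.copy() for a in st.model.state_arrays()] for k, st in ae_states.items()
        }

    z0s = np.stack([t[0] for t in latent_triples]).astype(np.float32)
    mrs = np.stack([t[1] for t in latent_triples]).astype(np.float32)
    sps = np.stack([t[2] for t in latent_triples]).astype(np.float32)
    stats = {
        "DP": (float(z0s.mean()), float(z0s.std()) or 1.0),
        "MRI": (float(mrs.mean()), float(mrs.std()) or 1.0),
        "SIMFBP": (float(sps.mean()), float(sps.std()) or 1.0),
    }
    z0s = (z0s - stats["DP"][0]) / stats["DP"][1]
    mrs = (mrs - stats["MRI"][0]) / stats["MRI"][1]
    sps = (sps - stats["SIMFBP"][0]) / stats["SIMFBP"][1]
    conds = np.concatenate([mrs, sps], axis=1)

    zc = z0s.shape[1]
    unet = UNet(zc, conds.shape[1], config.width, config.temb_dim, config.seed,
                parametrization=config.parametrization)
    # robust clamp range for sampling: central 99.8% of the standardized
    # training latents (keeps the decoder inside its training distribution)
    lo, hi = np.percentile(z0s, [0.1, 99.9])
    state = LDMState(unet, config, stats, schedule=schedule,
                     z0_range=(float(lo), float(hi)))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 607]))
    opt = Adam(unet.parameters(), lr=config.learning_rate,
               clip_norm=config.grad_clip_norm or None)
    ema = EmaWeights(unet.parameters(), config.ema_decay) if config.ema_decay else None
    n = z0s.shape[0]
    lr0 = config.learning_rate
    for _step in range(config.steps):
        if config.lr_final_frac < 1.0 and config.steps > 1:
            opt.lr = lr0 * config.lr_final_frac ** (_step / (config.steps - 1))
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        t = rng.integers(1, schedule.T + 1, size=len(idx))
        z0 = z0s[idx]
        eps = rng.standard_normal(z0.shape).astype(np.float32)
        zt = q_sample(z0, t, eps, schedule).astype(np.float32)
        eps_hat, z0_hat = _model_predictions(unet, Tensor(zt), t, Tensor(conds[idx]),
                                             schedule)
        if config.loss_mode == "combined":
            loss = loss_noise(Tensor(eps), eps_hat) + loss_image(Tensor(z0), z0_hat, weights)
        elif config.loss_mode == "noise_space":
            # gamma-identity form: image-scale L2 == gamma_t * noise-scale L2
            g = gamma_t(schedule, t).reshape(-1, 1, 1, 1, 1).astype(np.float32)
            diff = Tensor(eps) - eps_hat
            loss = (
                loss_noise(Tensor(eps), eps_hat)
                + (1.0 - weights.alpha_ms) * (Tensor(g) * diff * diff).mean()
            )
            if weights.alpha_ms > 0:
                loss = loss + weights.alpha_ms * (
                    1.0 - ms_ssim(Tensor(z0), z0_hat, weights.ms_scales,
                                  weights.ms_window, weights.data_range)
                )
        else:
            raise DiffusionError(f"unknown loss_mode {config.loss_mode!r}")
        unet.zero_grad()
        loss.backward()
        opt.step()
        if ema is not None:
            ema.update()
        state.loss_history.append(loss.item())

    if ema is not None:
        ema.copy_to()
    if ae_snapshot is not None:
        for k, st in ae_states.items():
            for before, after in zip(ae_snapshot[k], st.model.state_arrays()):
                assert np.array_equal(before, after), "autoencoder weights changed"
    return state


# ---------------------------------------------------------------------------
# sampling


def sample(
    cond: tuple[np.ndarray, np.ndarray],
    schedule: NoiseSchedule,
    state: LDMState,
    method: str = "strided",
    n_steps: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Draw a clean DP latent given (z_MR, z_SP) conditioning.

    ``ancestral`` runs the full reverse chain with the posterior variance;
    ``strided`` runs a deterministic skipped-step trajectory over ``n_steps``
    sub-sampled timesteps (with ``n_steps == T`` it visits every timestep).
    Reproducible given (cond, state, seed).
    """
    if n_steps > schedule.T:
        raise DiffusionError("n_steps cannot exceed the schedule length")
    z_mr, z_sp = (np.asarray(c, dtype=np.float32) for c in cond)
    batched = z_mr.ndim == 5
    if not batched:
        z_mr, z_sp = z_mr[None], z_sp[None]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(z_mr.shape).astype(np.float32)

    def clamp(z0_hat):
        if state.z0_range is None:
            return z0_hat
        return np.clip(z0_hat, state.z0_range[0], state.z0_range[1])

    if method == "ancestral":
        for t in range(schedule.T, 0, -1):
            eps_hat = predict_noise(z, t, (z_mr, z_sp), state, schedule)
            ab_t = schedule.alpha_bar[t - 1]
            ab_prev = schedule.alpha_bar[t - 2] if t > 1 else 1.0
            z0_hat = clamp(estimate_z0(z, t, eps_hat, schedule))
            # posterior mean written in terms of the (clamped) z0 estimate
            beta_t = schedule.beta[t - 1]
            mu = (
                np.sqrt(ab_prev) * beta_t / (1.0 - ab_t) * z0_hat
                + np.sqrt(schedule.alpha[t - 1]) * (1.0 - ab_prev) / (1.0 - ab_t) * z
            )
            z = mu.astype(np.float32)
            if t > 1:
                z = z + np.sqrt(schedule.posterior_var[t - 1]) * rng.standard_normal(
                    z.shape
                ).astype(np.float32)
    elif method == "strided":
        ts = np.unique(np.linspace(1, schedule.T, n_steps).round().astype(int))[::-1]
        for i, t in enumerate(ts):
            eps_hat = predict_noise(z, int(t), (z_mr, z_sp), state, schedule)
            z0_hat = clamp(estimate_z0(z, int(t), eps_hat, schedule))
            if i + 1 < len(ts):
                t_prev = int(ts[i + 1])
                ab_t = schedule.alpha_bar[t - 1]
                ab_prev = schedule.alpha_bar[t_prev - 1]
                # eps consistent with the clamped estimate keeps the
                # trajectory coherent
                eps_adj = (z - np.sqrt(ab_t) * z0_hat) / np.sqrt(1.0 - ab_t)
                z = np.sqrt(ab_prev) * z0_hat + np.sqrt(1.0 - ab_prev) * eps_adj
            else:
                z = z0_hat
        z = z.astype(np.float32)
    else:
        raise DiffusionError(f"unknown sampling method {method!r}")
    if not np.all(np.isfinite(z)):
        raise DiffusionError("sampler produced non-finite values")
    return z if batched else z[0]


# ---------------------------------------------------------------------------
# checkpointing


def save_ldm(state: LDMState, path) -> None:
    """Single-file checkpoint: U-Net weights with embedded config, schedule
    and latent-normalization JSON."""
    meta = {
        "config": asdict(state.config),
        "latent_stats": state.latent_stats,
        "z0_range": state.z0_range,
        "unet": {
            "latent_channels": state.unet.latent_channels,
            "cond_channels": state.unet.cond_channels,
            "temb_dim": state.unet.temb_dim,
            "parametrization": state.unet.parametrization,
        },
        "schedule": None
        if state.schedule is None
        else {"T": state.schedule.T, "beta": state.schedule.beta.tolist()},
    }
    arrays = {f"w{i}": a for i, a in enumerate(state.unet.state_arrays())}
    np.savez(str(path),
             __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_ldm(path) -> LDMState:
    with np.load(str(path)) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = [npz[f"w{i}"] for i in range(len(npz.files) - 1)]
    cfg = DiffusionConfig(**meta["config"])
    u = meta["unet"]
    unet = UNet(u["latent_channels"], u["cond_channels"], cfg.width,
                u["temb_dim"], cfg.seed, parametrization=u["parametrization"])
    unet.load_state_arrays(arrays)
    schedule = None
    if meta["schedule"] is not None:
        beta = np.asarray(meta["schedule"]["beta"])
        alpha = 1.0 - beta
        alpha_bar = np.cumprod(alpha)
        prev = np.concatenate([[1.0], alpha_bar[:-1]])
        schedule = NoiseSchedule(meta["schedule"]["T"], beta, alpha, alpha_bar,
                                 (1.0 - prev) / (1.0 - alpha_bar) * beta)
    stats = {k: tuple(v) for k, v in meta["latent_stats"].items()}
    z0_range = tuple(meta["z0_range"]) if meta.get("z0_range") else None
    return LDMState(unet, cfg, stats, schedule=schedule, z0_range=z0_range)


# ---------------------------------------------------------------------------
# end-to-end volume recovery


@dataclass(frozen=True)
class SuperResolveConfig:
    tile_shape: tuple[int, int, int] = (32, 32, 32)
    overlap: int = 0
    method: str = "strided"
    n_steps: int = 25
    n_avg: int = 3  # samples averaged in latent space (conditional-mean estimate)
    seed: int = 0


def super_resolve(
    fbp_vol: VoxelVolume,
    mri_vol: VoxelVolume,
    ae_states: dict[str, AutoencoderState],
    ldm_state: LDMState,
    schedule: NoiseSchedule,
    config: SuperResolveConfig = SuperResolveConfig(),
) -> VoxelVolume:
    """MRI-guided resolution recovery of a low-resolution PET volume.

    Tiles both inputs (which must be co-registered on the same grid), encodes
    each tile with its modality autoencoder, samples the corresponding DP
    latent from the conditional diffusion model, decodes, and reassembles.
    The output is clipped at zero and tagged RECOVERED.
    """
    if fbp_vol.shape != mri_vol.shape or fbp_vol.spacing_mm != mri_vol.spacing_mm:
        raise DiffusionError("PET and MRI must share grid shape and spacing")
    pet_tiles = tile_volume(fbp_vol, config.tile_shape, config.overlap)
    mri_tiles = tile_volume(mri_vol, config.tile_shape, config.overlap)
    z_sp = np.stack(
        [encode(t, ae_states["SIMFBP"], o, "SIMFBP").values for o, t in pet_tiles]
    )
    z_mr = np.stack(
        [encode(t, ae_states["MRI"], o, "MRI").values for o, t in mri_tiles]
    )
    z_sp = ldm_state.standardize(z_sp, "SIMFBP").astype(np.float32)
    z_mr = ldm_state.standardize(z_mr, "MRI").astype(np.float32)
    draws = [
        sample((z_mr, z_sp), schedule, ldm_state, config.method, config.n_steps,
               config.seed + 1000 * k)
        for k in range(max(1, config.n_avg))
    ]
    z0 = np.mean(draws, axis=0)
    z0 = ldm_state.destandardize(z0, "DP")
    out_tiles = []
    for (origin, _), z in zip(pet_tiles, z0):
        block = LatentBlock(z, origin, "DP")
        out_tiles.append((origin, decode(block, ae_states["DP"])))
    data = untile_volume(out_tiles, fbp_vol.shape, config.overlap)
    return VoxelVolume(np.clip(data, 0.0, None), fbp_vol.spacing_mm, "RECOVERED")
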