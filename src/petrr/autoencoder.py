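"""Stage-1 compression: modality-specific 3D variational autoencoders.

One autoencoder per modality (simulated scan, digital phantom, MRI) compresses
image sub-volumes by a factor of 4 per axis into a small multi-channel latent
grid (e.g. 64^3 -> 16^3, or 32^3 -> 8^3 at toy scale).  The diffusion stage
operates entirely on these latents.

Training minimises a composite objective: L1 reconstruction error, a weak KL
regularization of the latent posterior towards N(0, I), and optional
perceptual (feature-space distance against a small fixed seeded convolutional
extractor) and patch-adversarial terms.  The perceptual and adversarial terms
are stabilizers and are off by default at toy scale; each can be enabled
independently through the config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor, pixel_shuffle3d, pixel_unshuffle3d
from .nn.layers import Conv3d, Module, SiLU, Sequential
from .nn.optim import Adam, EmaWeights
from .volumes import VoxelVolume

__all__ = [
    "LatentBlock",
    "AutoencoderConfig",
    "Autoencoder",
    "AutoencoderState",
    "tile_volume",
    "untile_volume",
    "train_autoencoder",
    "encode",
    "decode",
    "save_state",
    "load_state",
]

COMPRESSION_FACTOR = 4  # per axis


class CompressionError(ValueError):
    pass


@dataclass
class LatentBlock:
    """Latent representation of one image sub-volume."""

    values: np.ndarray  # (channels, d, h, w)
    origin: tuple[int, int, int]
    modality: str

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]


@dataclass(frozen=True)
class AutoencoderConfig:
    sub_volume_shape: tuple[int, int, int] = (32, 32, 32)
    latent_channels: int = 3
    width: int = 16
    epochs: int = 2
    batch_size: int = 4
    learning_rate: float = 2e-3
    lr_decay: float = 1.0  # multiplicative, per epoch
    grad_clip_norm: float = 1.0  # 0 disables
    ema_decay: float = 0.995  # EMA weights used after training; 0 disables
    l1_weight: float = 1.0
    kl_weight: float = 1e-6
    perceptual_weight: float = 0.0
    adversarial_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s % COMPRESSION_FACTOR for s in self.sub_volume_shape):
            raise CompressionError(
                f"sub_volume_shape must be divisible by {COMPRESSION_FACTOR}"
            )


# ---------------------------------------------------------------------------
# tiling


def tile_volume(
    vol: VoxelVolume | np.ndarray, sub_shape: tuple[int, int, int], overlap: int = 0
) -> list[tuple[tuple[int, int, int], np.ndarray]]:
    """Cover a volume with sub-volumes of ``sub_shape`` and record origins.

    Tiles advance by ``sub_shape - overlap``; the final tile along each axis is
    clamped so the full volume is covered exactly.
    """
    data = vol.data if isinstance(vol, VoxelVolume) else np.asarray(vol)
    shape = data.shape
    if any(ss > s for ss, s in zip(sub_shape, shape)):
        raise CompressionError(f"sub_shape {sub_shape} exceeds volume shape {shape}")
    if any(overlap >= ss for ss in sub_shape):
        raise CompressionError("overlap must be smaller than the tile")

    def starts(size, sub):
        step = sub - overlap
        s = list(range(0, size - sub + 1, step))
        if s[-1] != size - sub:
            s.append(size - sub)
        return s

    tiles = []
    for i in starts(shape[0], sub_shape[0]):
        for j in starts(shape[1], sub_shape[1]):
            for k in starts(shape[2], sub_shape[2]):
                sl = (slice(i, i + sub_shape[0]), slice(j, j + sub_shape[1]),
                      slice(k, k + sub_shape[2]))
                tiles.append(((i, j, k), data[sl].copy()))
    return tiles


def _blend_weight(sub_shape, overlap: int) -> np.ndarray:
    """Separable positive blending window; ramps over the overlap region."""
    axes = []
    for n in sub_shape:
        w = np.ones(n)
        if overlap > 0:
            ramp = (np.arange(overlap) + 1.0) / (overlap + 1.0)
            w[:overlap] = np.minimum(w[:overlap], ramp)
            w[-overlap:] = np.minimum(w[-overlap:], ramp[::-1])
        axes.append(w)
    return axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def untile_volume(
    tiles: list[tuple[tuple[int, int, int], np.ndarray]],
    full_shape: tuple[int, int, int],
    overlap: int = 0,
) -> np.ndarray:
    """Reassemble tiles into a volume with normalized overlap blending.

    The accumulated blend weights are normalized voxel-wise, so the round trip
    ``untile(tile(v)) == v`` is exact wherever tiles agree.
    """
    acc = np.zeros(full_shape, dtype=np.float64)
    wacc = np.zeros(full_shape, dtype=np.float64)
    for origin, tile in tiles:
        w = _blend_weight(tile.shape, overlap)
        sl = tuple(slice(o, o + s) for o, s in zip(origin, tile.shape))
        acc[sl] += tile * w
        wacc[sl] += w
    if np.any(wacc == 0):
        raise CompressionError("tiles do not cover the full volume")
    return acc / wacc


# ---------------------------------------------------------------------------
# model


class _Encoder(Module):
    """Space-to-depth encoder: lossless sub-voxel folding followed by learned
    channel compression, so no spatial information is discarded before the
    network decides what to keep."""

    def __init__(self, cfg: AutoencoderConfig, rng: np.random.Generator):
        w = cfg.width
        self.c1 = Conv3d(8, w, rng=rng)
        self.c2 = Conv3d(8 * w, w, rng=rng)
        self.c3 = Conv3d(w, 2 * cfg.latent_channels, rng=rng)  # -> (mu, logvar)
        # start with a near-deterministic posterior (sigma ~ e^-3)
        self.c3.bias.data[cfg.latent_channels :] = -6.0

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.c1(pixel_unshuffle3d(x)).silu()
        h = self.c2(pixel_unshuffle3d(h)).silu()
        both = self.c3(h)
        c = both.shape[1] // 2
        mu = Tensor._make(both.data[:, :c], [(both, lambda g, c=c: _pad_ch(g, both.shape, 0, c))])
        lv = Tensor._make(both.data[:, c:], [(both, lambda g, c=c: _pad_ch(g, both.shape, c, None))])
        return mu, lv


def _pad_ch(g, shape, start, stop):
    out = np.zeros(shape, dtype=g.dtype)
    out[:, slice(start, stop)] = g
    return out


class _Decoder(Module):
    """Sub-voxel (pixel-shuffle) decoder: most computation stays at coarse
    resolution and fine detail is emitted through dedicated channels, which
    reconstructs thin structures (the cortical ribbon) far more sharply than
    nearest-neighbour upsampling at equal cost."""

    def __init__(self, cfg: AutoencoderConfig, rng: np.random.Generator):
        w = cfg.width
        w2 = max(w // 2, 8)
        self.c1 = Conv3d(cfg.latent_channels, w, rng=rng)
        self.c1b = Conv3d(w, w, rng=rng)
        self.up1 = Conv3d(w, 8 * w2, rng=rng)
        self.c2 = Conv3d(w2, w2, rng=rng)
        self.up2 = Conv3d(w2, 8 * 4, rng=rng)
        self.c3 = Conv3d(4, 1, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        h = self.c1(z).silu()
        h = self.c1b(h).silu()
        h = pixel_shuffle3d(self.up1(h)).silu()
        h = self.c2(h).silu()
        h = pixel_shuffle3d(self.up2(h)).silu()
        return self.c3(h)


class _PatchDiscriminator(Module):
    def __init__(self, rng: np.random.Generator, width: int = 8):
        self.c1 = Conv3d(1, width, stride=2, rng=rng)
        self.c2 = Conv3d(width, width, stride=2, rng=rng)
        self.c3 = Conv3d(width, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.c3(self.c2(self.c1(x).silu()).silu())


class _PerceptualNet(Module):
    """Fixed (seeded, untrained) convolutional feature extractor."""

    def __init__(self, rng: np.random.Generator, width: int = 8):
        self.net = Sequential(Conv3d(1, width, stride=2, rng=rng), SiLU(),
                              Conv3d(width, width, stride=2, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class Autoencoder(Module):
    def __init__(self, cfg: AutoencoderConfig, modality: str):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
        self.cfg = cfg
        self.modality = modality
        self.encoder = _Encoder(cfg, rng)
        self.decoder = _Decoder(cfg, rng)

    def encode_mu(self, x: Tensor) -> tuple[Tensor, Tensor]:
        return self.encoder(x)

    def decode(self, z: Tensor) -> Tensor:
        return self.decoder(z)


@dataclass
class AutoencoderState:
    """Serializable trained model: config, modality and flat weight arrays."""

    config: AutoencoderConfig
    modality: str
    model: Autoencoder
    final_loss: float = float("nan")
    loss_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# training and inference


def train_autoencoder(
    dataset: list[np.ndarray] | list[VoxelVolume],
    config: AutoencoderConfig,
    modality: str,
    max_steps: int | None = None,
) -> AutoencoderState:
    """Train a modality-specific autoencoder on image sub-volumes.

    ``dataset`` is a list of sub-volumes (3D arrays of the configured tile
    shape) or of :class:`VoxelVolume` objects tagged with one modality.
    Raises on mixed modalities.  Deterministic given (dataset order, config).
    """
    if not dataset:
        raise CompressionError("empty training dataset")
    tiles = []
    for item in dataset:
        if isinstance(item, VoxelVolume):
            if item.modality != modality:
                raise CompressionError(
                    f"mixed modalities: expected {modality}, got {item.modality}"
                )
            tiles.append(item.data)
        else:
            tiles.append(np.asarray(item, dtype=np.float64))
    if any(t.shape != tuple(config.sub_volume_shape) for t in tiles):
        raise CompressionError("all tiles must match config.sub_volume_shape")

    model = Autoencoder(config, modality)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 211]))
    opt = Adam(model.parameters(), lr=config.learning_rate,
               clip_norm=config.grad_clip_norm or None)
    ema = EmaWeights(model.parameters(), config.ema_decay) if config.ema_decay else None
    disc = opt_d = None
    if config.adversarial_weight > 0:
        disc = _PatchDiscriminator(np.random.default_rng(np.random.SeedSequence([config.seed, 307])))
        opt_d = Adam(disc.parameters(), lr=config.learning_rate)
    percep = None
    if config.perceptual_weight > 0:
        percep = _PerceptualNet(np.random.default_rng(np.random.SeedSequence([config.seed, 401])))

    x_all = np.stack(tiles)[:, None].astype(np.float32)  # (n, 1, d, h, w)
    n = x_all.shape[0]
    history: list[float] = []
    steps_done = 0
    for _epoch in range(config.epochs):
        if _epoch:
            opt.lr *= config.lr_decay
            if opt_d is not None:
                opt_d.lr *= config.lr_decay
        order = rng.permutation(n)
        for s in range(0, n, config.batch_size):
            if max_steps is not None and steps_done >= max_steps:
                break
            xb = Tensor(x_all[order[s : s + config.batch_size]])
            mu, logvar = model.encode_mu(xb)
            z = mu + (logvar.clamp_min(-10.0) * 0.5).exp() * Tensor(
                rng.standard_normal(mu.shape).astype(np.float32)
            )
            recon = model.decode(z)
            loss = config.l1_weight * (recon - xb).abs().mean()
            if config.kl_weight > 0:
                lv = logvar.clamp_min(-10.0)
                kl = 0.5 * (mu * mu + lv.exp() - lv - 1.0).mean()
                loss = loss + config.kl_weight * kl
            if percep is not None:
                diff = percep(recon) - percep(xb).detach()
                loss = loss + config.perceptual_weight * (diff * diff).mean()
            if disc is not None:
                # generator side: fool the discriminator (least-squares GAN)
                fake_score = disc(recon)
                loss = loss + config.adversarial_weight * ((fake_score - 1.0) ** 2).mean()
            model.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                ema.update()
            history.append(loss.item())
            steps_done += 1
            if disc is not None:
                d_loss = (
                    ((disc(xb) - 1.0) ** 2).mean()
                    + (disc(Tensor(recon.data)) ** 2).mean()
                )
                disc.zero_grad()
                d_loss.backward()
                opt_d.step()
    if ema is not None:
        ema.copy_to()
    return AutoencoderState(config, modality, model,
                            final_loss=history[-1] if history else float("nan"),
                            loss_history=history)


def encode(sub_volume: np.ndarray | VoxelVolume, state: AutoencoderState,
           origin: tuple[int, int, int] = (0, 0, 0),
           modality: str | None = None) -> LatentBlock:
    """Encode one sub-volume to its latent block (posterior mean)."""
    if isinstance(sub_volume, VoxelVolume):
        modality = modality or sub_volume.modality
        sub_volume = sub_volume.data
    if modality is not None and modality != state.modality:
        raise CompressionError(
            f"modality mismatch: volume {modality}, model {state.modality}"
        )
    x = Tensor(np.asarray(sub_volume, dtype=np.float32)[None, None])
    mu, _ = state.model.encode_mu(x)
    return LatentBlock(mu.data[0].copy(), tuple(origin), state.modality)


def decode(block: LatentBlock, state: AutoencoderState) -> np.ndarray:
    """Decode a latent block back to image space (3D array)."""
    if block.modality != state.modality:
        raise CompressionError(
            f"modality mismatch: block {block.modality}, model {state.modality}"
        )
    z = Tensor(np.asarray(block.values, dtype=np.float32)[None])
    return state.model.decode(z).data[0, 0].copy()


# ---------------------------------------------------------------------------
# serialization


def save_state(state: AutoencoderState, path: str | Path) -> None:
    """Single-file checkpoint: npz of weight arrays with embedded JSON config."""
    arrays = {f"w{i}": a for i, a in enumerate(state.model.state_arrays())}
    meta = json.dumps(
        {"config": asdict(state.config), "modality": state.modality,
         "final_loss": state.final_loss}
    )
    np.savez(str(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_state(path: str | Path) -> AutoencoderState:
    with np.load(str(path)) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = [npz[f"w{i}"] for i in range(len(npz.files) - 1)]
    cfg_d = meta["config"]
    cfg_d["sub_volume_shape"] = tuple(cfg_d["sub_volume_shape"])
    cfg = AutoencoderConfig(**cfg_d)
    state = AutoencoderState(cfg, meta["modality"], Autoencoder(cfg, meta["modality"]),
                             final_loss=meta["final_loss"])
    state.model.load_state_arrays(arrays)
    return state
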