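"""Attention-guided U-Net enhancer for breathing mel spectrograms.

Trained unpaired against a set of well-characterized ("clear")
spectrograms using a relativistic least-squares global critic, a
least-squares local patch critic, and self-feature-preserving (SFP)
losses computed from a fixed convolutional encoder with instance
normalization. Total generator loss:
``L = L_SFP_local + L_SFP_global + L_G_local + L_G_global``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Conv2d, Module, Tensor
from .nn import autograd as ag

__all__ = [
    "GanConfig",
    "attention_map",
    "UNetGenerator",
    "PatchCritic",
    "SfpEncoder",
    "relativistic_global_losses",
    "relativistic_sigmoid",
    "local_losses_from_scores",
    "local_patch_losses",
    "sfp_loss",
    "train_gan",
    "enhance",
]


@dataclass
class GanConfig:
    image_size: int = 64
    base_channels: int = 8
    crop_size: int = 16
    n_crops: int = 4
    lr: float = 1e-4
    steps: int = 200
    batch_size: int = 4
    seed: int = 0
    attention: bool = True
    local_discriminator: bool = True

    def __post_init__(self) -> None:
        if self.crop_size >= self.image_size:
            raise ValueError("crop_size must be smaller than image_size")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


def attention_map(spec: np.ndarray) -> np.ndarray:
    """Min-max normalized copy of the (single-channel) spectrogram in [0, 1].

    Stands in for the red-channel attention map of an RGB rendering;
    constant inputs map to all zeros to avoid 0/0.
    """
    spec = np.asarray(spec, dtype=np.float64)
    span = np.ptp(spec)
    if span == 0:
        return np.zeros_like(spec)
    return (spec - spec.min()) / span


def _pool_map(att: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool an (B,1,H,W) attention map down by a power-of-two factor."""
    if factor == 1:
        return att
    b, c, h, w = att.shape
    return att.reshape(b, c, h // factor, factor, w // factor, factor).mean(axis=(3, 5))


class UNetGenerator(Module):
    """Residual attention U-Net; output = clamp(input + correction, 0, 1)."""

    def __init__(
        self,
        base_channels: int = 8,
        attention: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        c = base_channels
        self.attention = attention
        self.enc1 = Conv2d(1, c, 3, rng=rng)
        self.enc2 = Conv2d(c, 2 * c, 3, stride=2, rng=rng)
        self.enc3 = Conv2d(2 * c, 4 * c, 3, stride=2, rng=rng)
        self.mid = Conv2d(4 * c, 4 * c, 3, rng=rng)
        self.dec2 = Conv2d(4 * c + 2 * c, 2 * c, 3, rng=rng)
        self.dec1 = Conv2d(2 * c + c, c, 3, rng=rng)
        self.out = Conv2d(c, 1, 3, rng=rng, gain=0.2)

    def __call__(self, x: Tensor, att: np.ndarray | None = None) -> Tensor:
        use_att = self.attention and att is not None

        def gate(t: Tensor, factor: int) -> Tensor:
            if not use_att:
                return t
            return t * Tensor(_pool_map(att, factor))

        e1 = gate(ag.leaky_relu(self.enc1(x)), 1)
        e2 = gate(ag.leaky_relu(self.enc2(e1)), 2)
        e3 = gate(ag.leaky_relu(self.enc3(e2)), 4)
        m = ag.leaky_relu(self.mid(e3))
        d2 = ag.leaky_relu(self.dec2(ag.concat([ag.upsample_nearest2x(m), e2], axis=1)))
        d2 = gate(d2, 2)
        d1 = ag.leaky_relu(self.dec1(ag.concat([ag.upsample_nearest2x(d2), e1], axis=1)))
        d1 = gate(d1, 1)
        return ag.clamp(x + self.out(d1), 0.0, 1.0)


class PatchCritic(Module):
    """Small strided PatchGAN; per-sample score = mean of the output map."""

    def __init__(self, base_channels: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c = base_channels
        self.c1 = Conv2d(1, c, 3, stride=2, rng=rng)
        self.c2 = Conv2d(c, 2 * c, 3, stride=2, rng=rng)
        self.c3 = Conv2d(2 * c, 1, 3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.leaky_relu(self.c1(x))
        h = ag.leaky_relu(self.c2(h))
        return ag.mean(self.c3(h), axis=(1, 2, 3))


class SfpEncoder(Module):
    """Fixed, seeded random convolutional feature stack for the SFP loss."""

    def __init__(self, base_channels: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.c1 = Conv2d(1, c, 3, stride=2, rng=rng)
        self.c2 = Conv2d(c, 2 * c, 3, stride=2, rng=rng)
        self.c3 = Conv2d(2 * c, 2 * c, 3, rng=rng)
        self.freeze()

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.leaky_relu(self.c1(x))
        h = ag.leaky_relu(self.c2(h))
        return self.c3(h)


def relativistic_sigmoid(scores_a: np.ndarray, scores_b: np.ndarray) -> np.ndarray:
    """Original sigmoid form: sigma(C(a) - E[C(b)]) (kept for reference/tests)."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(scores_a) - np.mean(scores_b))))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def relativistic_global_losses(c_real, c_fake) -> tuple[Tensor, Tensor]:
    """Least-squares relativistic losses on critic score batches.

    D_Ra(a, b) = C(a) - E[C(b)] (sigmoid replaced by the LS surrogate);
    L_D = E[(D_Ra(r,f) - 1)^2] + E[D_Ra(f,r)^2],
    L_G = E[(D_Ra(f,r) - 1)^2] + E[D_Ra(r,f)^2].
    """
    c_real, c_fake = _as_tensor(c_real), _as_tensor(c_fake)
    if c_real.data.size == 0 or c_fake.data.size == 0:
        raise ValueError("score batches must be non-empty")
    d_rf = c_real - ag.mean(c_fake)
    d_fr = c_fake - ag.mean(c_real)
    one = Tensor(1.0)
    l_d = ag.mean((d_rf - one) ** 2) + ag.mean(d_fr**2)
    l_g = ag.mean((d_fr - one) ** 2) + ag.mean(d_rf**2)
    return l_d, l_g


def local_losses_from_scores(d_real, d_fake) -> tuple[Tensor, Tensor]:
    """Plain LSGAN patch losses from critic score batches."""
    d_real, d_fake = _as_tensor(d_real), _as_tensor(d_fake)
    one = Tensor(1.0)
    l_d = ag.mean((d_real - one) ** 2) + ag.mean(d_fake**2)
    l_g = ag.mean((d_fake - one) ** 2)
    return l_d, l_g


def sample_crop_positions(
    rng: np.random.Generator, image_size: int, crop_size: int, n_crops: int
) -> list[tuple[int, int]]:
    hi = image_size - crop_size + 1
    return [tuple(rng.integers(0, hi, size=2)) for _ in range(n_crops)]


def take_crops(x: Tensor, positions: list[tuple[int, int]], crop_size: int) -> Tensor:
    crops = [
        x[:, :, i : i + crop_size, j : j + crop_size] for i, j in positions
    ]
    return ag.concat(crops, axis=0)


def local_patch_losses(
    real: Tensor,
    fake: Tensor,
    critic: PatchCritic,
    crop_size: int,
    n_crops: int,
    rng: np.random.Generator,
    positions: list[tuple[int, int]] | None = None,
) -> tuple[Tensor, Tensor, list[tuple[int, int]]]:
    """LSGAN losses on randomly cropped local patches (uniform positions)."""
    if n_crops < 1:
        raise ValueError("n_crops must be >= 1")
    image_size = real.data.shape[-1]
    if crop_size >= image_size:
        raise ValueError("crop_size must be smaller than the image")
    if positions is None:
        positions = sample_crop_positions(rng, image_size, crop_size, n_crops)
    d_real = critic(take_crops(real, positions, crop_size))
    d_fake = critic(take_crops(fake, positions, crop_size))
    l_d, l_g = local_losses_from_scores(d_real, d_fake)
    return l_d, l_g, positions


def sfp_loss(i_img: Tensor, g_img: Tensor, encoder: SfpEncoder) -> Tensor:
    """Mean squared distance between instance-normalized encoder features."""
    f_i = ag.instance_norm(encoder(i_img))
    f_g = ag.instance_norm(encoder(g_img))
    return ag.mean((f_i - f_g) ** 2)


def _prep(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None]
    return x


def train_gan(
    noisy_specs: np.ndarray,
    clear_specs: np.ndarray,
    config: GanConfig | None = None,
) -> tuple[UNetGenerator, dict, list[dict]]:
    """Alternating critic/generator training on unpaired spectrogram sets.

    Returns the generator, the auxiliary modules (critics + SFP encoder),
    and a per-step history whose ``l_gan`` entry is exactly the sum of
    the logged enabled loss components.
    """
    cfg = config or GanConfig()
    noisy, clear = _prep(noisy_specs), _prep(clear_specs)
    if noisy.shape[0] == 0 or clear.shape[0] == 0:
        raise ValueError("both training sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    gen = UNetGenerator(cfg.base_channels, attention=cfg.attention, rng=rng)
    critic_g = PatchCritic(cfg.base_channels, rng=rng)
    critic_l = PatchCritic(cfg.base_channels, rng=rng)
    encoder = SfpEncoder(cfg.base_channels, seed=cfg.seed + 1)

    d_params = critic_g.parameters() + (
        critic_l.parameters() if cfg.local_discriminator else []
    )
    opt_d = Adam(d_params, lr=cfg.lr)
    opt_g = Adam(gen.parameters(), lr=cfg.lr)

    history: list[dict] = []
    for step in range(cfg.steps):
        bi = rng.integers(0, noisy.shape[0], size=cfg.batch_size)
        bj = rng.integers(0, clear.shape[0], size=cfg.batch_size)
        x = Tensor(noisy[bi])
        real = Tensor(clear[bj])
        att = (
            np.stack([attention_map(noisy[k, 0])[None] for k in bi])
            if cfg.attention
            else None
        )
        positions = sample_crop_positions(rng, cfg.image_size, cfg.crop_size, cfg.n_crops)

        fake = gen(x, att)
        fake_detached = Tensor(fake.data.copy())

        # --- critic step ---
        for m in (critic_g, critic_l):
            m.zero_grad()
        l_d_global, _ = relativistic_global_losses(critic_g(real), critic_g(fake_detached))
        loss_d = l_d_global
        l_d_local_val = None
        if cfg.local_discriminator:
            l_d_local, _, _ = local_patch_losses(
                real, fake_detached, critic_l, cfg.crop_size, cfg.n_crops, rng, positions
            )
            loss_d = loss_d + l_d_local
            l_d_local_val = l_d_local.item()
        loss_d.backward()
        opt_d.step()

        # --- generator step ---
        gen.zero_grad()
        for m in (critic_g, critic_l):
            m.zero_grad()
        _, l_g_global = relativistic_global_losses(critic_g(real), critic_g(fake))
        sfp_global = sfp_loss(x, fake, encoder)
        terms = {"l_g_global": l_g_global, "l_sfp_global": sfp_global}
        if cfg.local_discriminator:
            _, l_g_local, _ = local_patch_losses(
                real, fake, critic_l, cfg.crop_size, cfg.n_crops, rng, positions
            )
            sfp_local = sfp_loss(
                take_crops(x, positions, cfg.crop_size),
                take_crops(fake, positions, cfg.crop_size),
                encoder,
            )
            terms["l_g_local"] = l_g_local
            terms["l_sfp_local"] = sfp_local
        loss_g = None
        for t in terms.values():
            loss_g = t if loss_g is None else loss_g + t
        loss_g.backward()
        opt_g.step()

        row = {name: t.item() for name, t in terms.items()}
        row["l_gan"] = sum(row.values())  # additivity holds exactly by construction
        row["l_d_global"] = l_d_global.item()
        if l_d_local_val is not None:
            row["l_d_local"] = l_d_local_val
        row["step"] = step
        history.append(row)

    aux = {"critic_global": critic_g, "critic_local": critic_l, "sfp_encoder": encoder}
    return gen, aux, history


def enhance(
    generator: UNetGenerator, specs: np.ndarray, batch_size: int = 16
) -> np.ndarray:
    """Run the generator over an array of spectrogram images."""
    x = _prep(specs)
    outs = []
    for k in range(0, x.shape[0], batch_size):
        chunk = x[k : k + batch_size]
        att = (
            np.stack([attention_map(c[0])[None] for c in chunk])
            if generator.attention
            else None
        )
        outs.append(generator(Tensor(chunk), att).data)
    out = np.concatenate(outs, axis=0)
    return out[:, 0] if np.asarray(specs).ndim == 3 else out
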