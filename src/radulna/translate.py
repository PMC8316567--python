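"""Paired image-to-image translation from X-ray-like images to clean bone
DRRs (the "GAN-DRR" producer).

A conditional adversarial setup in the pix2pix mould: a generator maps the
degraded image to a clean bone DRR and is trained with a weighted sum of an
adversarial term and an L1 reconstruction term (reconstruction weight well
above the adversarial weight, following the paired-translation convention
of a 100:1 ratio); a patch discriminator judges (input, candidate) patch
pairs as real or fake.

At desk scale both networks are fully connected: the generator is a
residual MLP (output = input + learned correction), the discriminator a
shared MLP applied to every non-overlapping patch.  Images are normalized
by a single dataset-level scale recorded in the trained state — not
per-image — so absolute intensity information survives translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DRRImage, ParameterError, StateError
from .nn import MLP, Adam, Tensor, bce_with_logits, concat, l1_loss


@dataclass
class TranslatorConfig:
    image_shape: tuple = (32, 32)
    gen_hidden: tuple = (256,)
    disc_patch: int = 8
    disc_hidden: tuple = (64,)
    adversarial_weight: float = 1.0
    l1_weight: float = 100.0
    lr: float = 2e-4
    epochs: int = 15
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adversarial_weight < 0 or self.l1_weight < 0:
            raise ParameterError("loss weights must be >= 0")
        if self.adversarial_weight == 0 and self.l1_weight == 0:
            raise ParameterError("at least one loss weight must be > 0")
        h, w = self.image_shape
        if h % self.disc_patch or w % self.disc_patch:
            raise ParameterError("disc_patch must divide the image shape")

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.image_shape))


@dataclass
class TranslatorState:
    config: TranslatorConfig
    generator: MLP
    discriminator: MLP
    norm_scale: float = 1.0
    history: list = field(default_factory=list)  # per-epoch loss/val records

    @classmethod
    def initialize(cls, cfg: TranslatorConfig) -> "TranslatorState":
        rng = np.random.default_rng(cfg.seed)
        gen = MLP([cfg.n_pixels, *cfg.gen_hidden, cfg.n_pixels], rng,
                  activation="relu")
        p = cfg.disc_patch
        disc = MLP([2 * p * p, *cfg.disc_hidden, 1], rng, activation="leaky_relu")
        return cls(config=cfg, generator=gen, discriminator=disc)


def _patches(t: Tensor, shape: tuple, p: int) -> Tensor:
    """(N, H*W) -> (N * H/p * W/p, p*p) non-overlapping patches."""
    h, w = shape
    n = t.data.shape[0]
    return (
        t.reshape(n, h // p, p, w // p, p)
        .transpose((0, 1, 3, 2, 4))
        .reshape(n * (h // p) * (w // p), p * p)
    )


def _disc_logits(state: TranslatorState, x: Tensor, y: Tensor) -> Tensor:
    cfg = state.config
    px = _patches(x, cfg.image_shape, cfg.disc_patch)
    py = _patches(y, cfg.image_shape, cfg.disc_patch)
    return state.discriminator(concat([px, py], axis=1))


def _generate(state: TranslatorState, x: Tensor) -> Tensor:
    """Residual generator: input plus learned correction."""
    return x + state.generator(x)


def _flatten_images(images, cfg: TranslatorConfig) -> np.ndarray:
    arr = np.stack([np.asarray(im.pixels, dtype=np.float64) for im in images])
    if arr.shape[1:] != tuple(cfg.image_shape):
        raise ParameterError(
            f"images of shape {arr.shape[1:]} do not match config {cfg.image_shape}"
        )
    return arr.reshape(arr.shape[0], -1)


def mae_images(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(a) - np.asarray(b))))


def train_translator(
    train_pairs: list,
    cfg: TranslatorConfig,
    val_pairs: list | None = None,
) -> TranslatorState:
    """Train on (X-ray-like, clean bone DRR) pairs.

    ``val_pairs`` (raw, non-augmented) are used only to log a per-epoch
    validation MAE; with none given, the last training pair is reused for
    the log so the record structure is stable.  Deterministic given
    ``cfg.seed`` (up to floating-point associativity).
    """
    if len(train_pairs) < 1:
        raise ParameterError("need at least one training pair")
    for xr, dr in train_pairs:
        if xr.pixels.shape != dr.pixels.shape:
            raise ParameterError("pair members must share shape")

    state = TranslatorState.initialize(cfg)
    x_all = _flatten_images([p[0] for p in train_pairs], cfg)
    y_all = _flatten_images([p[1] for p in train_pairs], cfg)
    scale = float(max(np.abs(x_all).max(), np.abs(y_all).max(), 1e-12))
    state.norm_scale = scale
    x_all = x_all / scale
    y_all = y_all / scale

    if val_pairs:
        xv = _flatten_images([p[0] for p in val_pairs], cfg) / scale
        yv = _flatten_images([p[1] for p in val_pairs], cfg) / scale
    else:
        xv, yv = x_all[-1:], y_all[-1:]

    rng = np.random.default_rng(cfg.seed + 1)
    opt_g = Adam(state.generator.parameters(), lr=cfg.lr)
    opt_d = Adam(state.discriminator.parameters(), lr=cfg.lr)
    n = x_all.shape[0]
    steps_per_epoch = max(1, n // cfg.batch_size)

    def check(value: float, epoch: int, term: str) -> None:
        if not np.isfinite(value):
            raise StateError(f"non-finite {term} loss at epoch {epoch}")

    for epoch in range(int(cfg.epochs)):
        g_losses, d_losses = [], []
        for _ in range(steps_per_epoch):
            idx = rng.integers(0, n, size=min(cfg.batch_size, n))
            xb, yb = Tensor(x_all[idx]), Tensor(y_all[idx])

            if cfg.adversarial_weight > 0:
                fake = _generate(state, xb)
                d_real = bce_with_logits(_disc_logits(state, xb, yb), 1.0)
                d_fake = bce_with_logits(
                    _disc_logits(state, xb, Tensor(fake.data)), 0.0
                )
                d_loss = d_real + d_fake
                check(d_loss.item(), epoch, "discriminator")
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()
                d_losses.append(d_loss.item())

            fake = _generate(state, xb)
            g_loss = cfg.l1_weight * l1_loss(fake, yb)
            if cfg.adversarial_weight > 0:
                g_loss = g_loss + cfg.adversarial_weight * bce_with_logits(
                    _disc_logits(state, xb, fake), 1.0
                )
            check(g_loss.item(), epoch, "generator")
            opt_g.zero_grad()
            g_loss.backward()
            opt_g.step()
            g_losses.append(g_loss.item())

        pred_v = _generate(state, Tensor(xv)).data
        val_mae = mae_images(np.clip(pred_v, 0.0, None), yv) * scale  # original units
        state.history.append(
            {
                "epoch": epoch,
                "g_loss": float(np.mean(g_losses)),
                "d_loss": float(np.mean(d_losses)) if d_losses else 0.0,
                "val_mae": float(val_mae),
            }
        )
    return state


def translate(xray: DRRImage, state: TranslatorState) -> DRRImage:
    """Single deterministic forward pass; output clipped at zero."""
    cfg = state.config
    x = np.asarray(xray.pixels, dtype=np.float64)
    if x.shape != tuple(cfg.image_shape):
        raise ParameterError(
            f"input shape {x.shape} does not match training shape {cfg.image_shape}"
        )
    xb = x.reshape(1, -1) / state.norm_scale
    out = _generate(state, Tensor(xb)).data.reshape(cfg.image_shape)
    out = np.clip(out * state.norm_scale, 0.0, None)
    return DRRImage(pixels=out, pixel_spacing=xray.pixel_spacing)
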