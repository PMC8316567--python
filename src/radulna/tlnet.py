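"""TL-embedding reconstruction network: 3D label autoencoder plus 2D-to-
latent predictor, trained in three stages.

The network has three parts sharing one latent space:

* encoder ``E``: one-hot 3D label grid -> latent vector,
* decoder ``D``: latent vector -> per-voxel class logits,
* predictor ``P``: 2D DRR -> latent vector.

Training stages (all Adam):

1. Denoising autoencoder on labels: ``E`` and ``D`` are trained on
   Gaussian-noise-corrupted one-hot labels to reconstruct the clean label,
   with an L1 penalty on the latent code.
2. Predictor training with ``D`` frozen: ``P`` learns to map a DRR into the
   latent space such that the frozen decoder reconstructs the label.
3. Fine-tuning of ``P`` and ``D`` with ``E`` frozen, adding a latent-
   consistency term comparing ``E(y)`` with ``E(D(P(x)))``.

Loss formulas (softmax cross-entropy ``L_label``, lambda1 = lambda2 = 1e-4
by default):

    L_step1 = L_label(D(E(y_noised)), y) + lambda1 * |E(y_noised)|_1
    L_step2 = L_label(D(P(x)), y)       + lambda1 * |P(x)|_1
    L_step3 = L_step2 + lambda2 * |E(y) - E(D(P(x)))|_2

The consistency norm is the Euclidean norm (not squared) by default, with a
squared variant behind ``squared_consistency``.  Since ``D`` emits logits
while ``E`` consumes one-hot-like grids, ``E(D(P(x)))`` feeds the softmax
of the decoder logits into the encoder, keeping the term differentiable.
Latent norms are averaged over the batch so loss magnitudes are independent
of batch size; cross-entropy is averaged over voxels so lambda values are
resolution-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DataError, LabelVolume, ParameterError, StateError
from .nn import MLP, Adam, Tensor, l1_norm, l2_norm, softmax, softmax_cross_entropy


@dataclass
class TLNetConfig:
    label_shape: tuple = (16, 16, 16)
    image_shape: tuple = (32, 32)
    n_classes: int = 3
    latent_dim: int = 64
    encoder_hidden: tuple = (128,)
    decoder_hidden: tuple = (128,)
    predictor_hidden: tuple = (128,)
    lambda1: float = 1e-4
    lambda2: float = 1e-4
    noise_sigma: float = 0.1
    stage_iters: tuple = (1200, 1200, 600)
    stage_lrs: tuple = (1e-4, 1e-4, 1e-5)
    batch_size: int = 8
    seed: int = 0
    squared_consistency: bool = False
    fov_halfwidth: float = 40.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ParameterError("lambda1 and lambda2 must be >= 0")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if any(int(i) < 1 for i in self.stage_iters):
            raise ParameterError("stage iteration counts must be >= 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.label_shape))

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.image_shape))

    @property
    def label_spacing(self) -> np.ndarray:
        n = np.asarray(self.label_shape)
        return 2.0 * self.fov_halfwidth / (n - 1)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot encode an integer class array along a trailing class axis."""
    y = np.asarray(y)
    if y.min() < 0 or y.max() >= n_classes:
        raise DataError(f"class values must be in [0, {n_classes})")
    out = np.zeros(y.shape + (n_classes,), dtype=np.float64)
    np.put_along_axis(out, y[..., None].astype(np.intp), 1.0, axis=-1)
    return out


def label_loss(logits, y) -> "Tensor | float":
    """Softmax cross-entropy averaged over voxels.

    ``logits`` has a trailing class axis; ``y`` holds integer classes of the
    matching shape.  Returns a float for array input, a Tensor for Tensor
    input (so it can sit inside a training graph).
    """
    is_tensor = isinstance(logits, Tensor)
    t = logits if is_tensor else Tensor(np.asarray(logits, dtype=np.float64))
    c = t.data.shape[-1]
    flat = t.reshape(-1, c)
    target = np.asarray(y).reshape(-1)
    if target.shape[0] != flat.data.shape[0]:
        raise DataError("logits and label shapes are inconsistent")
    if target.size and (target.min() < 0 or target.max() >= c):
        raise DataError(f"class values must be in [0, {c})")
    out = softmax_cross_entropy(flat, target)
    return out if is_tensor else out.item()


def _latent_l1(z: Tensor) -> Tensor:
    n_batch = z.data.shape[0] if z.data.ndim == 2 else 1
    return l1_norm(z) * (1.0 / n_batch)


def loss_step1(
    y, y_noised, encoder, decoder, lambda1: float, n_classes: int = 3
) -> Tensor:
    """Denoising-autoencoder loss: reconstruction CE plus latent L1."""
    z = encoder(y_noised if isinstance(y_noised, Tensor) else Tensor(y_noised))
    logits = decoder(z)
    ce = softmax_cross_entropy(
        logits.reshape(-1, n_classes), np.asarray(y).reshape(-1)
    )
    return ce + lambda1 * _latent_l1(z)


def loss_step2(
    x,
    y,
    predictor,
    decoder,
    lambda1: float,
    n_classes: int = 3,
    *,
    decoder_frozen: bool = True,
) -> Tensor:
    """Predictor loss through the frozen decoder."""
    if not decoder_frozen:
        raise StateError("stage-2 loss requires the decoder to be frozen")
    z = predictor(x if isinstance(x, Tensor) else Tensor(x))
    logits = decoder(z)
    ce = softmax_cross_entropy(
        logits.reshape(-1, n_classes), np.asarray(y).reshape(-1)
    )
    return ce + lambda1 * _latent_l1(z)


def loss_step3(
    x,
    y,
    encoder,
    decoder,
    predictor,
    lambda1: float,
    lambda2: float,
    n_classes: int = 3,
    *,
    encoder_frozen: bool = True,
    squared: bool = False,
) -> Tensor:
    """Fine-tuning loss: stage-2 terms plus latent consistency.

    The consistency term compares the encoding of the true label with the
    encoding of the decoder's (softmaxed) reconstruction; gradients flow to
    the predictor and decoder while the encoder stays frozen.
    """
    if not encoder_frozen:
        raise StateError("stage-3 loss requires the encoder to be frozen")
    z = predictor(x if isinstance(x, Tensor) else Tensor(x))
    logits = decoder(z)
    c = n_classes
    flat_logits = logits.reshape(-1, c)
    target = np.asarray(y).reshape(-1)
    ce = softmax_cross_entropy(flat_logits, target)
    loss = ce + lambda1 * _latent_l1(z)
    if lambda2 != 0.0:
        n_batch = z.data.shape[0] if z.data.ndim == 2 else 1
        y_oh = one_hot(np.asarray(y).reshape(n_batch, -1), c).reshape(n_batch, -1)
        e_y = encoder(Tensor(y_oh))
        probs = softmax(flat_logits, axis=-1).reshape(n_batch, -1)
        e_rec = encoder(probs)
        diff = e_y - e_rec
        if squared:
            cons = (diff * diff).sum() * (1.0 / n_batch)
        else:
            cons = l2_norm(diff) * (1.0 / n_batch)
        loss = loss + lambda2 * cons
    return loss


@dataclass
class TLNetState:
    """Trained (or training) TL-net parameters plus logs and stage flags."""

    config: TLNetConfig
    encoder: MLP
    decoder: MLP
    predictor: MLP
    logs: list = field(default_factory=list)
    stages_completed: list = field(default_factory=list)
    #: SHA-256 of each network's parameter bytes at every stage boundary,
    #: recorded so freezing contracts are machine-checkable after training.
    checksums: dict = field(default_factory=dict)

    def record_checksums(self, key: str) -> None:
        import hashlib

        self.checksums[key] = {
            name: hashlib.sha256(net.state_bytes()).hexdigest()
            for name, net in (
                ("encoder", self.encoder),
                ("decoder", self.decoder),
                ("predictor", self.predictor),
            )
        }

    @classmethod
    def initialize(cls, cfg: TLNetConfig) -> "TLNetState":
        rng = np.random.default_rng(cfg.seed)
        vc = cfg.n_voxels * cfg.n_classes
        enc = MLP([vc, *cfg.encoder_hidden, cfg.latent_dim], rng)
        dec = MLP([cfg.latent_dim, *cfg.decoder_hidden, vc], rng)
        pred = MLP([cfg.n_pixels, *cfg.predictor_hidden, cfg.latent_dim], rng)
        return cls(config=cfg, encoder=enc, decoder=dec, predictor=pred)

    def decoder_logits(self, z: Tensor) -> Tensor:
        c = self.config.n_classes
        out = self.decoder(z)
        return out.reshape(-1, c)


def _prep_images(x: np.ndarray, cfg: TLNetConfig) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x.reshape(-1, cfg.n_pixels)


def _prep_labels(y: np.ndarray, cfg: TLNetConfig) -> np.ndarray:
    y = np.asarray(y)
    return y.reshape(-1, cfg.n_voxels)


def train(
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TLNetConfig,
    state: TLNetState | None = None,
) -> TLNetState:
    """Run the three-stage training schedule.

    ``images``: (N, H, W) posed bone DRRs (already intensity-normalized);
    ``labels``: (N, D, H, W) integer class grids (the unposed normalized
    labels).  Stage order is enforced; a non-finite loss aborts with the
    stage and step named.
    """
    x = _prep_images(images, cfg)
    y = _prep_labels(labels, cfg)
    if x.shape[0] != y.shape[0] or x.shape[0] == 0:
        raise ParameterError("images and labels must be non-empty and paired")
    n = x.shape[0]
    c = cfg.n_classes
    y_flat_oh = one_hot(y, c).reshape(n, -1)

    if state is None:
        state = TLNetState.initialize(cfg)
    state.record_checksums("init")
    rng = np.random.default_rng(cfg.seed + 1)

    def check(loss_val: float, stage: int, step: int) -> None:
        if not np.isfinite(loss_val):
            raise StateError(f"non-finite loss at stage {stage}, step {step}")

    # ---- stage 1: denoising autoencoder on labels ------------------------
    opt = Adam(state.encoder.parameters() + state.decoder.parameters(),
               lr=cfg.stage_lrs[0])
    for step in range(int(cfg.stage_iters[0])):
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        noise = rng.normal(0.0, cfg.noise_sigma, size=(len(idx), y_flat_oh.shape[1]))
        y_noised = y_flat_oh[idx] + noise
        loss = loss_step1(
            y[idx], y_noised, state.encoder, state.decoder, cfg.lambda1, c
        )
        check(loss.item(), 1, step)
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.logs.append({"stage": 1, "step": step, "loss": loss.item()})
    state.stages_completed.append(1)
    state.record_checksums("stage1")

    # ---- stage 2: predictor with frozen decoder --------------------------
    opt = Adam(state.predictor.parameters(), lr=cfg.stage_lrs[1])
    for step in range(int(cfg.stage_iters[1])):
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        loss = loss_step2(
            x[idx], y[idx], state.predictor, state.decoder, cfg.lambda1, c
        )
        check(loss.item(), 2, step)
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.logs.append({"stage": 2, "step": step, "loss": loss.item()})
    state.stages_completed.append(2)
    state.record_checksums("stage2")

    # ---- stage 3: fine-tune predictor+decoder, encoder frozen ------------
    opt = Adam(state.predictor.parameters() + state.decoder.parameters(),
               lr=cfg.stage_lrs[2])
    for step in range(int(cfg.stage_iters[2])):
        idx = rng.integers(0, n, size=min(cfg.batch_size, n))
        loss = loss_step3(
            x[idx],
            y[idx],
            state.encoder,
            state.decoder,
            state.predictor,
            cfg.lambda1,
            cfg.lambda2,
            squared=cfg.squared_consistency,
            n_classes=c,
        )
        check(loss.item(), 3, step)
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.logs.append({"stage": 3, "step": step, "loss": loss.item()})
    state.stages_completed.append(3)
    state.record_checksums("stage3")
    return state


def predict_logits(x: np.ndarray, state: TLNetState) -> np.ndarray:
    """Per-voxel class logits for a batch (or single) DRR."""
    cfg = state.config
    xb = _prep_images(x, cfg)
    z = state.predictor(Tensor(xb))
    logits = state.decoder(z)
    return logits.data.reshape(xb.shape[0], *cfg.label_shape, cfg.n_classes)


def reconstruct(x: np.ndarray, state: TLNetState) -> LabelVolume:
    """Reconstruct a single label volume from one DRR via argmax D(P(x))."""
    if 2 not in state.stages_completed:
        raise StateError("predictor is untrained: complete stage 2 before reconstruct")
    cfg = state.config
    logits = predict_logits(np.asarray(x)[None] if np.asarray(x).ndim == 2 else x, state)
    classes = np.argmax(logits[0], axis=-1).astype(np.uint8)
    spacing = cfg.label_spacing
    n = np.asarray(cfg.label_shape)
    origin = -spacing * (n - 1) / 2.0
    return LabelVolume(voxels=classes, spacing=spacing, origin=origin)
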