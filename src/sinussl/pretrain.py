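"""Self-supervised pretraining: the skip-connected encoder-decoder learns to
predict each volume's residual map, so the encoder acquires features that
localize anomalies before it ever sees a label.

The volume x is the network input and its residual |x - A(x)| is the
regression target (binary cross-entropy on soft targets by default). Spatial
augmentations (random affine, flips) are applied jointly to input and target
so the localization signal survives augmentation; Gaussian noise perturbs the
input only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .networks import ModelState
from .nn import make_optimizer
from .nn import core as _nncore
from .preprocess import MSVolume
from .uad import LossSpec, ResidualVolume


@dataclass
class AugmentConfig:
    enabled: bool = True
    probability: float = 0.5
    max_rotation_deg: float = 10.0
    max_translation_frac: float = 0.06
    noise_sd: float = 0.05


@dataclass
class PretrainConfig:
    loss: LossSpec = field(default_factory=lambda: LossSpec("BCE"))
    epochs: int = 500
    warmup_epochs: int = 20
    peak_lr: float = 0.2
    batch_size: int = 256
    optimizer: str = "layerwise_adaptive"  # or "adam_family"
    augmentations: AugmentConfig = field(default_factory=AugmentConfig)
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.loss, str):
            self.loss = LossSpec(self.loss)
        if not (0 <= self.warmup_epochs < self.epochs):
            raise ValueError("warmup_epochs must satisfy 0 <= warmup < epochs")
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")
        if self.optimizer not in ("layerwise_adaptive", "adam_family"):
            raise ValueError("optimizer must be layerwise_adaptive or adam_family")


def lr_schedule(epoch: int, config: PretrainConfig) -> float:
    """Linear warmup to ``peak_lr`` followed by cosine decay to zero.

    The ramp reaches the peak exactly at ``epoch == warmup_epochs`` and the
    cosine reaches zero at the final epoch, so the two pieces join
    continuously at the peak.
    """
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    w, peak = config.warmup_epochs, config.peak_lr
    if epoch <= w and w > 0:
        return peak * epoch / w
    span = config.epochs - 1 - w
    if span <= 0:
        return peak
    return peak * 0.5 * (1.0 + np.cos(np.pi * (epoch - w) / span))


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    ax, ay, az = angles
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rx @ ry @ rz


def _apply_affine(grid: np.ndarray, matrix: np.ndarray, shift: np.ndarray) -> np.ndarray:
    center = (np.array(grid.shape) - 1) / 2.0
    offset = center - matrix @ (center + shift)
    return ndimage.affine_transform(grid, matrix, offset=offset, order=1,
                                    mode="nearest")


def augment_pair(volume: np.ndarray, target: np.ndarray | None,
                 rng: np.random.Generator,
                 config: AugmentConfig | None = None) -> tuple[np.ndarray, np.ndarray | None]:
    """Jointly augment an input volume and its (optional) spatial target.

    Affine and flip transforms use identical sampled parameters for both
    grids; Gaussian noise is added to the input only. Each augmentation fires
    independently with ``config.probability``. Outputs are clipped to [0, 1].
    """
    if config is None:
        config = AugmentConfig()
    if volume.shape != (target.shape if target is not None else volume.shape):
        raise ValueError("volume and target shapes differ")
    fire = rng.random(3) < config.probability
    vol, tgt = volume, target
    if fire[0]:  # random affine
        angles = rng.uniform(-1, 1, size=3) * np.deg2rad(config.max_rotation_deg)
        shift = rng.uniform(-1, 1, size=3) * config.max_translation_frac * vol.shape[0]
        matrix = _rotation_matrix(angles)
        vol = _apply_affine(vol, matrix, shift)
        if tgt is not None:
            tgt = _apply_affine(tgt, matrix, shift)
    if fire[1]:  # flip
        axis = int(rng.integers(3))
        vol = np.flip(vol, axis=axis).copy()
        if tgt is not None:
            tgt = np.flip(tgt, axis=axis).copy()
    if fire[2]:  # Gaussian noise on the input only
        vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, 1.0)
    if tgt is not None:
        tgt = np.clip(tgt, 0.0, 1.0)
    return vol, tgt


def pretrain_reconstructor(encoder: ModelState, decoder: ModelState,
                           pairs: list[tuple[MSVolume, ResidualVolume]],
                           config: PretrainConfig) -> tuple[ModelState, ModelState]:
    """Train (E, D) to predict residual maps from volumes.

    A ``val_fraction`` tail of the shuffled pairs is held out; the parameters
    with the lowest validation loss are the ones returned. Encoder and
    decoder come back with provenance ``ssl_pretrained``.
    """
    if encoder.kind != "encoder" or decoder.kind != "decoder":
        raise ValueError("pretrain_reconstructor needs (encoder, decoder) states")
    for vol, res in pairs:
        if res.source_volume_id != vol.uid:
            raise ValueError(
                f"pair misaligned: volume {vol.uid} vs residual "
                f"{res.source_volume_id}")
    if not pairs:
        raise ValueError("no pairs to pretrain on")
    loss_fn = config.loss.fn
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(config.val_fraction * len(pairs)))) if len(pairs) > 4 else 0
    val_idx = order[len(pairs) - n_val:]
    train_idx = order[:len(pairs) - n_val]

    params = encoder.module.parameters() + decoder.module.parameters()
    opt_name = "lars" if config.optimizer == "layerwise_adaptive" else "adam"
    opt = make_optimizer(opt_name, params)

    x_all = np.stack([pairs[i][0].data
                      for i in range(len(pairs))])[:, None].astype(_nncore.DTYPE)
    y_all = np.stack([pairs[i][1].data
                      for i in range(len(pairs))])[:, None].astype(_nncore.DTYPE)

    def run_batch(xb, yb, lr):
        bottleneck, skips = encoder.module.forward_map(xb, training=True)
        pred = decoder.module.forward(bottleneck, skips, training=True)
        value, grad = loss_fn(pred, yb)
        opt.zero_grad()
        g_bottleneck, g_skips = decoder.module.backward(grad)
        encoder.module.backward_map(g_bottleneck, g_skips)
        opt.step(lr)
        return value

    def val_loss():
        total, batches = 0.0, 0
        for start in range(0, len(val_idx), config.batch_size):
            sel = val_idx[start:start + config.batch_size]
            bottleneck, skips = encoder.module.forward_map(x_all[sel], training=False)
            pred = decoder.module.forward(bottleneck, skips, training=False)
            total += loss_fn(pred, y_all[sel])[0]
            batches += 1
        return total / max(batches, 1)

    curve = []
    best = None
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        ep_order = rng.permutation(train_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(ep_order), config.batch_size):
            sel = ep_order[start:start + config.batch_size]
            if config.augmentations.enabled:
                xs, ys = [], []
                for i in sel:
                    v, t = augment_pair(x_all[i, 0], y_all[i, 0], rng,
                                        config.augmentations)
                    xs.append(v)
                    ys.append(t)
                xb, yb = np.stack(xs)[:, None], np.stack(ys)[:, None]
            else:
                xb, yb = x_all[sel], y_all[sel]
            epoch_loss += run_batch(xb, yb, lr)
            n_batches += 1
        vloss = val_loss() if n_val else epoch_loss / max(n_batches, 1)
        curve.append({"epoch": epoch, "lr": lr,
                      "loss": epoch_loss / max(n_batches, 1), "val_loss": vloss})
        if best is None or vloss < best[0]:
            best = (vloss, epoch,
                    copy.deepcopy(encoder.module.state_arrays()),
                    copy.deepcopy(decoder.module.state_arrays()))
    if best is not None:
        encoder.module.load_state_arrays(best[2])
        decoder.module.load_state_arrays(best[3])
    encoder.advance("ssl_pretrained")
    decoder.advance("ssl_pretrained")
    record = {"stage": "ssl_pretrain", "loss": config.loss.kind,
              "epochs": config.epochs, "optimizer": config.optimizer,
              "best_epoch": best[1] if best else None,
              "curve": curve, "seed": config.seed, "n_pairs": len(pairs)}
    encoder.history.append(record)
    decoder.history.append(record)
    return encoder, decoder
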