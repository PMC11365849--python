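"""Unsupervised anomaly detection stage: train the autoencoder on normal
volumes only, then turn its reconstruction errors on the unlabelled pool into
residual volumes — the pseudo segmentation masks driving self-supervision.

The residual of a volume x under a trained autoencoder A is the voxel-wise
absolute error |x - A(x)|. Because both x and A(x) live in [0, 1], residuals
do too, which makes them valid soft targets for binary cross-entropy later.
An optional 3D median filter (default kernel 5 in the ablation pipeline)
suppresses speckle in the residual before it is used as a target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .networks import ModelState
from .nn import RECON_LOSSES, Adam
from .nn import core as _nncore
from .preprocess import NORMAL, MSVolume, save_volume


@dataclass
class LossSpec:
    kind: str = "L1"

    def __post_init__(self):
        if self.kind not in RECON_LOSSES:
            raise ValueError(f"loss kind must be one of {sorted(RECON_LOSSES)}")

    @property
    def fn(self):
        return RECON_LOSSES[self.kind]


@dataclass
class ResidualVolume:
    data: np.ndarray
    source_volume_id: str
    cae_checkpoint_id: str = ""
    median_kernel: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("residual values must lie in [0, 1]")


def _stack(volumes: list[MSVolume]) -> np.ndarray:
    return np.stack([v.data for v in volumes])[:, None].astype(_nncore.DTYPE)


def train_cae(model: ModelState, normal_set: list[MSVolume],
              loss: LossSpec | None = None, epochs: int = 20,
              batch_size: int = 16, lr: float = 1e-3, seed: int = 0) -> ModelState:
    """Train the autoencoder to reconstruct normal volumes (no augmentation).

    The input model must be freshly initialized; the returned state carries
    provenance ``cae_trained`` and a per-epoch loss curve in ``history``.
    """
    if model.kind != "cae":
        raise ValueError(f"expected a cae model, got kind={model.kind!r}")
    if model.provenance != "random_init":
        raise ValueError(f"train_cae requires random_init provenance, "
                         f"got {model.provenance!r}")
    if not normal_set:
        raise ValueError("normal_set is empty")
    bad = [v.uid for v in normal_set if v.label != NORMAL]
    if bad:
        raise ValueError(f"non-normal volumes in CAE training set: {bad[:5]}")
    if loss is None:
        loss = LossSpec("L1")
    rng = np.random.default_rng(seed)
    opt = Adam(model.module.parameters())
    x_all = _stack(normal_set)
    n = x_all.shape[0]
    curve = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            xb = x_all[order[start:start + batch_size]]
            pred = model.module.forward(xb, training=True)
            value, grad = loss.fn(pred, xb)
            opt.zero_grad()
            model.module.backward(grad)
            opt.step(lr)
            epoch_loss += value
            n_batches += 1
        curve.append(epoch_loss / n_batches)
    if epochs > 0:
        model.advance("cae_trained")
        model.history.append({"stage": "train_cae", "loss": loss.kind,
                              "epochs": epochs, "curve": curve, "seed": seed,
                              "n_train": n})
    return model


def compute_residual(model: ModelState, volume: MSVolume) -> ResidualVolume:
    """Voxel-wise |x - A(x)|, no thresholding."""
    if model.provenance != "cae_trained":
        raise ValueError("compute_residual requires a cae_trained model")
    x = volume.data[None, None].astype(_nncore.DTYPE)
    recon = model.module.forward(x, training=False)[0, 0]
    if recon.shape != volume.data.shape:
        raise ValueError("reconstruction shape mismatch")
    residual = np.abs(volume.data - np.clip(recon, 0.0, 1.0))
    return ResidualVolume(data=residual, source_volume_id=volume.uid,
                          cae_checkpoint_id=model.fingerprint)


def median_filter3d(volume: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Median over each kernel^3 neighborhood with reflect-padded borders."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return np.asarray(volume).copy()
    return ndimage.median_filter(np.asarray(volume, dtype=np.float64),
                                 size=kernel, mode="reflect")


def anomaly_score(residual: ResidualVolume | np.ndarray) -> float:
    """Mean voxel value of the residual; zero iff the residual is all-zero."""
    data = residual.data if isinstance(residual, ResidualVolume) else residual
    return float(np.mean(data))


def generate_residual_dataset(model: ModelState, unlabelled: list[MSVolume],
                              median_kernel: int | None = None,
                              out_dir: Path | str | None = None,
                              ) -> list[ResidualVolume]:
    """Residuals (optionally median-filtered) for every unlabelled volume."""
    if model.provenance != "cae_trained":
        raise ValueError("generate_residual_dataset requires a cae_trained model")
    out: list[ResidualVolume] = []
    for volume in unlabelled:
        try:
            res = compute_residual(model, volume)
            if median_kernel is not None:
                res = ResidualVolume(data=median_filter3d(res.data, median_kernel),
                                     source_volume_id=res.source_volume_id,
                                     cae_checkpoint_id=res.cae_checkpoint_id,
                                     median_kernel=median_kernel)
            out.append(res)
        except Exception as exc:
            raise RuntimeError(f"residual generation failed for {volume.uid}") from exc
    if out_dir is not None:
        out_dir = Path(out_dir)
        for res in out:
            save_volume(out_dir / f"{res.source_volume_id}_residual.nii.gz", res.data)
            sidecar = {"source_volume_id": res.source_volume_id,
                       "cae_checkpoint_id": res.cae_checkpoint_id,
                       "median_kernel": res.median_kernel}
            (out_dir / f"{res.source_volume_id}_residual.json").write_text(
                json.dumps(sidecar, indent=1))
    return out


def dice_overlap(binary_a: np.ndarray, binary_b: np.ndarray) -> float:
    """Dice coefficient between two binary masks (1.0 for two empty masks)."""
    a = np.asarray(binary_a, dtype=bool)
    b = np.asarray(binary_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def localize_lesion(residual: ResidualVolume, percentile: float = 95.0) -> np.ndarray:
    """Binary localization map: voxels above the residual's own percentile."""
    data = residual.data
    return data > np.percentile(data, percentile)
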