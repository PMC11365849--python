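"""Supervised fine-tuning of the encoder for normal-vs-anomalous
classification, plus the learning-curve and CAE-training-set experiments.

The decoder is discarded; the (pretrained or random) encoder gets a fresh
MLP head and is trained end-to-end with cross-entropy on a class-stratified
fraction of the labelled training set. The checkpoint with the lowest
validation loss is kept. Metrics are computed on patient-disjoint test sets
and aggregated across folds with Student-t confidence intervals.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import MetricsReport, auprc, auroc, f1
from .networks import ModelState, build_classifier
from .nn import AdamW, softmax, softmax_cross_entropy
from .nn import core as _nncore
from .preprocess import (ANOMALOUS, DatasetSplit, MSVolume,
                         stratified_fraction)
from .pretrain import AugmentConfig, augment_pair


@dataclass
class FinetuneConfig:
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 16
    label_fraction: float = 1.0
    init: str = "ssl_pretrained"  # or random_init
    hidden: int = 256
    augmentations: AugmentConfig = field(default_factory=AugmentConfig)
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0.0 < self.label_fraction <= 1.0):
            raise ValueError("label_fraction must lie in (0, 1]")
        if self.init not in ("ssl_pretrained", "random_init"):
            raise ValueError("init must be ssl_pretrained or random_init")


def _labels_array(volumes: list[MSVolume]) -> np.ndarray:
    return np.array([1 if v.label == ANOMALOUS else 0 for v in volumes], dtype=int)


def finetune_classifier(encoder: ModelState, split: DatasetSplit,
                        config: FinetuneConfig) -> tuple[ModelState, list[dict]]:
    """Train encoder + head on the label-fraction subset of ``split.train``.

    Returns the classifier (provenance ``finetuned``) restored to the epoch
    with minimum validation loss, and the per-epoch loss curve.
    """
    if encoder.provenance != config.init:
        raise ValueError(f"encoder provenance {encoder.provenance!r} does not "
                         f"match config.init {config.init!r}")
    split.check_patient_disjoint()
    if config.label_fraction < 1.0:
        train_set = stratified_fraction(split.train, config.label_fraction,
                                        seed=config.seed)
    else:
        train_set = list(split.train)
    labels = _labels_array(train_set)
    if len(np.unique(labels)) < 2:
        raise ValueError("a class is empty after label-fraction subsetting")

    classifier = build_classifier(encoder, hidden=config.hidden,
                                  seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    opt = AdamW(classifier.module.parameters())
    x_train = np.stack([v.data for v in train_set])[:, None].astype(_nncore.DTYPE)
    x_val = np.stack([v.data for v in split.validation])[:, None].astype(_nncore.DTYPE)
    y_val = _labels_array(split.validation)

    curve: list[dict] = []
    best = None
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            if config.augmentations.enabled:
                xb = np.stack([augment_pair(x_train[i, 0], None, rng,
                                            config.augmentations)[0]
                               for i in sel])[:, None]
            else:
                xb = x_train[sel]
            logits = classifier.module.forward(xb, training=True)
            value, grad = softmax_cross_entropy(logits, labels[sel])
            opt.zero_grad()
            classifier.module.backward(grad)
            opt.step(config.lr)
            epoch_loss += value
            n_batches += 1
        val_logits = classifier.module.forward(x_val, training=False)
        val_loss = softmax_cross_entropy(val_logits, y_val)[0]
        curve.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1),
                      "val_loss": val_loss})
        if best is None or val_loss < best[0]:
            best = (val_loss, epoch, copy.deepcopy(classifier.module.state_arrays()))
    if best is not None:
        classifier.module.load_state_arrays(best[2])
    classifier.advance("finetuned")
    classifier.history.append({"stage": "finetune", "init": config.init,
                               "label_fraction": config.label_fraction,
                               "best_epoch": best[1] if best else None,
                               "epochs": config.epochs, "seed": config.seed,
                               "n_train": len(train_set)})
    return classifier, curve


def evaluate_classifier(classifier: ModelState,
                        volumes: list[MSVolume]) -> dict:
    """Anomaly-class probabilities, argmax predictions and the metric triplet."""
    if classifier.kind != "classifier":
        raise ValueError("evaluate_classifier needs a classifier state")
    x = np.stack([v.data for v in volumes])[:, None].astype(_nncore.DTYPE)
    logits = classifier.module.forward(x, training=False)
    probs = softmax(logits)[:, 1]
    preds = (logits[:, 1] > logits[:, 0]).astype(int)
    labels = _labels_array(volumes)
    return {"scores": probs, "predictions": preds, "labels": labels,
            "auroc": auroc(probs, labels), "auprc": auprc(probs, labels),
            "f1": f1(preds, labels)}


# ---------------------------------------------------------------------------
# experiment harness

def _load_done(results_csv: Path | None) -> pd.DataFrame:
    if results_csv is not None and results_csv.exists():
        return pd.read_csv(results_csv)
    return pd.DataFrame()


def _cell_key(row: dict) -> tuple:
    return (row["fraction"], row["init"], row["fold"], row["seed"])


def run_learning_curve(encoders: dict[str, ModelState],
                       folds: list[DatasetSplit], fractions: list[float],
                       seeds: list[int], config: FinetuneConfig | None = None,
                       results_csv: Path | str | None = None,
                       ) -> tuple[pd.DataFrame, dict]:
    """Full factorial (fraction x init x fold x seed) fine-tuning sweep.

    ``encoders`` maps init name ('ssl_pretrained'/'random_init') to the
    encoder state to start from. Completed cells found in ``results_csv``
    are not retrained (resume by cell key). Returns the tidy results table
    and a dict of aggregated :class:`MetricsReport` summaries per
    (fraction, init).
    """
    if config is None:
        config = FinetuneConfig()
    results_csv = Path(results_csv) if results_csv is not None else None
    done = _load_done(results_csv)
    done_keys = {_cell_key(r) for r in done.to_dict("records")} if len(done) else set()
    rows = done.to_dict("records") if len(done) else []

    for fraction in fractions:
        for init, encoder in encoders.items():
            for fold_idx, split in enumerate(folds):
                for seed in seeds:
                    key = (fraction, init, fold_idx, seed)
                    if key in done_keys:
                        continue
                    cell_cfg = copy.deepcopy(config)
                    cell_cfg.label_fraction = fraction
                    cell_cfg.init = init
                    cell_cfg.seed = seed
                    split.check_patient_disjoint()
                    clf, _ = finetune_classifier(encoder, split, cell_cfg)
                    res = evaluate_classifier(clf, split.test)
                    rows.append({"fraction": fraction, "init": init,
                                 "fold": fold_idx, "seed": seed,
                                 "auroc": res["auroc"], "auprc": res["auprc"],
                                 "f1": res["f1"], "status": "ok",
                                 "fingerprint": clf.fingerprint})
                    if results_csv is not None:
                        pd.DataFrame(rows).to_csv(results_csv, index=False)
    table = pd.DataFrame(rows)
    reports: dict = {}
    for (fraction, init), group in table.groupby(["fraction", "init"]):
        report = MetricsReport(config_fingerprint=f"frac={fraction},init={init}")
        for row in group.itertuples(index=False):
            report.add_fold(row.auroc, row.auprc, row.f1)
        reports[(fraction, init)] = report.summary()
    return table, reports


def subset_normal_pool(normals: list[MSVolume], fraction: float,
                       seed: int) -> list[MSVolume]:
    """Seeded patient-permuted prefix of the normal pool (nested in fraction)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return list(normals)
    patients = sorted({v.patient_id for v in normals})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    flat = [v for idx in order for v in normals
            if v.patient_id == patients[idx]]
    m = int(np.floor(fraction * len(normals) + 0.5))
    return flat[:max(m, 1)]


def run_cae_fraction_ablation(cae_fractions: list[float], split: DatasetSplit,
                              unlabelled: list[MSVolume], seeds: list[int],
                              *, cae_builder, cae_trainer, unet_builder,
                              pretrainer, finetune_config: FinetuneConfig,
                              median_kernel: int | None = 5,
                              downstream_fraction: float = 0.1,
                              ) -> pd.DataFrame:
    """Retrain the whole chain for each normal-pool fraction (the study of how
    the autoencoder's training-set size propagates to downstream AUPRC).

    The stage constructors are injected so the desk and full profiles share
    the harness: ``cae_builder(seed)``, ``cae_trainer(state, normals, seed)``,
    ``unet_builder(seed)`` and ``pretrainer(encoder, decoder, pairs, seed)``.
    """
    from .uad import generate_residual_dataset

    normals = split.normal_train_subset
    rows = []
    for fraction in cae_fractions:
        for seed in seeds:
            pool = subset_normal_pool(normals, fraction, seed=seed)
            cae = cae_trainer(cae_builder(seed), pool, seed)
            residuals = generate_residual_dataset(cae, unlabelled,
                                                  median_kernel=median_kernel)
            pairs = list(zip(unlabelled, residuals))
            enc, dec = unet_builder(seed)
            enc, _ = pretrainer(enc, dec, pairs, seed)
            cfg = copy.deepcopy(finetune_config)
            cfg.label_fraction = downstream_fraction
            cfg.init = "ssl_pretrained"
            cfg.seed = seed
            clf, _ = finetune_classifier(enc, split, cfg)
            res = evaluate_classifier(clf, split.test)
            rows.append({"cae_fraction": fraction, "seed": seed,
                         "n_cae_train": len(pool),
                         "cae_checkpoint": cae.fingerprint,
                         "auroc": res["auroc"], "auprc": res["auprc"],
                         "f1": res["f1"]})
    return pd.DataFrame(rows)
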