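"""Synthetic desk-scale benchmark studies.

These drive the package's two headline experiments on phantoms, at sizes a
single CPU handles in minutes, and are shared by the test suite and the
reproduction script so the quantities are computed exactly one way:

* :func:`uad_localization_study` — train the autoencoder on normal phantoms
  only and measure (a) how well the mean residual separates held-out normal
  from anomalous phantoms (AUROC) and (b) how well thresholding the filtered
  residual at its 95th percentile overlaps the hidden lesion masks (Dice).
* :func:`ssl_benefit_study` — the label-efficiency contrast: fine-tuning
  from the residual-reconstruction pretrained encoder versus from random
  initialization at a small label fraction, plus the ablation over the
  fraction of the normal pool used to train the autoencoder.
"""

from __future__ import annotations

import copy

import numpy as np

from .finetune import (FinetuneConfig, evaluate_classifier,
                       finetune_classifier, subset_normal_pool)
from .metrics import auroc
from .networks import CAEConfig, UNetConfig, build_cae, build_unet
from .phantoms import PhantomParams, generate_dataset
from .preprocess import ANOMALOUS, make_cv_folds
from .pretrain import AugmentConfig, PretrainConfig, pretrain_reconstructor
from .uad import (LossSpec, anomaly_score, compute_residual, dice_overlap,
                  generate_residual_dataset, median_filter3d, train_cae)


def uad_localization_study(seed: int = 11, *, edge: int = 32,
                           n_train: int = 150, n_eval_per_class: int = 50,
                           epochs: int = 10, batch_size: int = 16,
                           lr: float = 1e-3, median_kernel: int = 5,
                           percentile: float = 95.0) -> dict:
    """Autoencoder anomaly detection and coarse localization on phantoms.

    Trains the CAE on ``n_train`` normal phantoms, then scores a held-out
    set of normal and anomalous phantoms by mean residual and localizes
    lesions by thresholding the median-filtered residual at its own
    ``percentile``. Returns separation AUROC and the median Dice overlap
    with the hidden lesion masks.
    """
    params = PhantomParams(cube_edge=edge)
    train_set, _, _ = generate_dataset(n_train, 0, 0, seed=seed, params=params)
    eval_set, _, _ = generate_dataset(n_eval_per_class, n_eval_per_class, 0,
                                      seed=seed + 1, params=params)
    cae = build_cae(CAEConfig(in_edge=edge, stage_channels=(8, 16, 32, 32),
                              latent_dim=64), seed=seed)
    cae = train_cae(cae, [s.volume for s in train_set], epochs=epochs,
                    batch_size=batch_size, lr=lr, seed=seed)
    scores, labels, dices = [], [], []
    for sample in eval_set:
        residual = compute_residual(cae, sample.volume)
        scores.append(anomaly_score(residual))
        labels.append(1 if sample.label == ANOMALOUS else 0)
        if sample.label == ANOMALOUS:
            filtered = median_filter3d(residual.data, median_kernel)
            loc = filtered > np.percentile(filtered, percentile)
            dices.append(dice_overlap(loc, sample.lesion_mask))
    return {
        "uad_auroc": auroc(scores, labels),
        "localization_dice_median": float(np.median(dices)),
        "final_train_l1": cae.history[-1]["curve"][-1],
        "n_train": n_train,
        "n_eval": 2 * n_eval_per_class,
    }


def _desk_chain(split, unlabelled, cae_fraction: float, seed: int, *,
                edge: int, cae_epochs: int, ssl_epochs: int,
                median_kernel: int, finetune_config: FinetuneConfig):
    """One autoencoder -> residual -> pretrain -> finetune chain."""
    pool = subset_normal_pool(split.normal_train_subset, cae_fraction, seed=seed)
    cae = build_cae(CAEConfig(in_edge=edge, stage_channels=(16, 32, 64),
                              latent_dim=128), seed=seed)
    cae = train_cae(cae, pool, epochs=cae_epochs, batch_size=8, lr=1e-3,
                    seed=seed)
    residuals = generate_residual_dataset(cae, unlabelled,
                                          median_kernel=median_kernel)
    encoder, decoder = build_unet(UNetConfig(width_factor=0.125), seed=seed)
    pcfg = PretrainConfig(loss=LossSpec("BCE"), epochs=ssl_epochs,
                          warmup_epochs=2, peak_lr=1e-3, batch_size=8,
                          optimizer="adam_family",
                          augmentations=AugmentConfig(enabled=True), seed=seed)
    encoder, _ = pretrain_reconstructor(encoder, decoder,
                                        list(zip(unlabelled, residuals)), pcfg)
    cfg = copy.deepcopy(finetune_config)
    cfg.init = "ssl_pretrained"
    cfg.seed = seed
    classifier, _ = finetune_classifier(encoder, split, cfg)
    return evaluate_classifier(classifier, split.test)


def ssl_benefit_study(seeds=(1, 2, 3), *, data_seed: int = 21,
                      split_seed: int = 5, edge: int = 16,
                      n_normal: int = 100, n_anomalous: int = 100,
                      n_unlabelled: int = 80, cae_epochs: int = 12,
                      ssl_epochs: int = 18, finetune_epochs: int = 30,
                      label_fraction: float = 0.1, median_kernel: int = 5,
                      cae_fractions=(0.2, 1.0)) -> dict:
    """Label-efficiency benchmark: pretrained vs random init, plus the
    normal-pool-fraction ablation, paired per seed.

    The full-pool chain serves both comparisons: its test AUPRC is the
    pretrained arm of the init contrast and the 100% arm of the ablation.
    Returns per-seed AUPRC lists and their means.
    """
    if 1.0 not in cae_fractions:
        raise ValueError("cae_fractions must include 1.0 (the full-pool arm)")
    params = PhantomParams(cube_edge=edge)
    labelled, unlabelled, _ = generate_dataset(
        n_normal, n_anomalous, n_unlabelled, 0.5, seed=data_seed, params=params)
    volumes = [s.volume for s in labelled]
    split = make_cv_folds(volumes, k=4, seed=split_seed)[0]
    fcfg = FinetuneConfig(lr=1e-3, epochs=finetune_epochs, batch_size=8,
                          label_fraction=label_fraction, hidden=64)

    results: dict = {"ssl": [], "random": [],
                     **{f"cae_{f:g}": [] for f in cae_fractions}}
    for seed in seeds:
        for fraction in cae_fractions:
            res = _desk_chain(split, unlabelled, fraction, seed, edge=edge,
                              cae_epochs=cae_epochs, ssl_epochs=ssl_epochs,
                              median_kernel=median_kernel, finetune_config=fcfg)
            results[f"cae_{fraction:g}"].append(res["auprc"])
            if fraction == 1.0:
                results["ssl"].append(res["auprc"])
        rand_cfg = copy.deepcopy(fcfg)
        rand_cfg.init = "random_init"
        rand_cfg.seed = seed
        enc_rand, _ = build_unet(UNetConfig(width_factor=0.125), seed=seed + 100)
        clf_rand, _ = finetune_classifier(enc_rand, split, rand_cfg)
        results["random"].append(evaluate_classifier(clf_rand, split.test)["auprc"])

    summary = {f"auprc_{name}_per_seed": [float(v) for v in vals]
               for name, vals in results.items()}
    summary.update({f"auprc_{name}_mean": float(np.mean(vals))
                    for name, vals in results.items()})
    summary["n_seeds"] = len(seeds)
    summary["label_fraction"] = label_fraction
    return summary
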