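"""End-to-end orchestration: phantom synthesis -> preprocessing/split ->
autoencoder training -> residual generation -> self-supervised pretraining ->
fine-tuning -> evaluation, with per-stage caching and one root seed.

Two scale profiles exist. ``desk`` runs the whole study on 16-voxel phantoms
with a width-1/8 encoder in minutes on one CPU; ``full`` holds the
full-scale conditions (64-voxel volumes, 500-epoch pretraining, batch 256).
Stage caching is keyed on a hash of the stage-relevant config; a rerun with
an unchanged config skips completed stages, and deleting an intermediate
artifact reruns only that stage and those downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .finetune import FinetuneConfig, run_learning_curve
from .networks import (CAEConfig, UNetConfig, build_cae, build_unet,
                       load_model_state)
from .phantoms import PhantomParams, generate_dataset
from .preprocess import make_cv_folds
from .pretrain import AugmentConfig, PretrainConfig, pretrain_reconstructor
from .uad import LossSpec, generate_residual_dataset, train_cae


@dataclass
class PhantomStageConfig:
    edge: int = 16
    n_normal: int = 100
    n_anomalous: int = 100
    n_unlabelled: int = 80
    anomaly_rate_unlabelled: float = 0.5


@dataclass
class CAEStageConfig:
    stage_channels: tuple[int, ...] = (16, 32, 64)
    latent_dim: int = 128
    epochs: int = 12
    batch_size: int = 8
    lr: float = 1e-3
    loss: str = "L1"


@dataclass
class ResidualStageConfig:
    median_kernel: int | None = 5


@dataclass
class UNetStageConfig:
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    width_factor: float = 0.125
    skip_connections: bool = True


@dataclass
class SSLStageConfig:
    loss: str = "BCE"
    epochs: int = 18
    warmup_epochs: int = 2
    peak_lr: float = 1e-3
    batch_size: int = 8
    optimizer: str = "adam_family"
    augment: bool = True


@dataclass
class FinetuneStageConfig:
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    label_fraction: float = 0.1
    hidden: int = 64
    augment: bool = True
    inits: tuple[str, ...] = ("ssl_pretrained", "random_init")


@dataclass
class RunConfig:
    phantom: PhantomStageConfig = field(default_factory=PhantomStageConfig)
    cae: CAEStageConfig = field(default_factory=CAEStageConfig)
    residual: ResidualStageConfig = field(default_factory=ResidualStageConfig)
    unet: UNetStageConfig = field(default_factory=UNetStageConfig)
    ssl: SSLStageConfig = field(default_factory=SSLStageConfig)
    finetune: FinetuneStageConfig = field(default_factory=FinetuneStageConfig)
    k_folds: int = 4
    fold_index: int = 0
    root_seed: int = 7
    output_dir: str = "sinussl_run"
    scale_profile: str = "desk"

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ValueError(f"unparseable config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for name, sub_cls in (("phantom", PhantomStageConfig),
                              ("cae", CAEStageConfig),
                              ("residual", ResidualStageConfig),
                              ("unet", UNetStageConfig),
                              ("ssl", SSLStageConfig),
                              ("finetune", FinetuneStageConfig)):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub_cls(**kwargs[name])
        return cls(**kwargs)


def desk_profile(**overrides) -> RunConfig:
    """Minutes-scale CPU profile: 16-voxel phantoms, width-1/8 encoder."""
    cfg = RunConfig(scale_profile="desk")
    return dataclasses.replace(cfg, **overrides)


def full_profile(**overrides) -> RunConfig:
    """Full-scale conditions: 64-voxel volumes, 500-epoch pretraining."""
    cfg = RunConfig(
        phantom=PhantomStageConfig(edge=64, n_normal=708, n_anomalous=487,
                                   n_unlabelled=1559),
        cae=CAEStageConfig(stage_channels=(16, 32, 64, 64), latent_dim=512,
                           epochs=100, batch_size=16, lr=1e-3),
        residual=ResidualStageConfig(median_kernel=5),
        unet=UNetStageConfig(width_factor=1.0),
        ssl=SSLStageConfig(epochs=500, warmup_epochs=20, peak_lr=0.2,
                           batch_size=256, optimizer="layerwise_adaptive"),
        finetune=FinetuneStageConfig(lr=1e-4, epochs=100, batch_size=16,
                                     hidden=256),
        k_folds=5,
        scale_profile="full",
    )
    return dataclasses.replace(cfg, **overrides)


def stage_seed(root_seed: int, stage_index: int) -> int:
    """Fan one root seed out to independent per-stage streams."""
    return (root_seed * 9973 + stage_index * 131) % (2 ** 31 - 1)


def validate_config(config: RunConfig) -> list[str]:
    """Static config checks; returns an empty list iff the config is runnable."""
    issues: list[str] = []
    p = config.phantom
    if p.edge % (2 ** len(config.cae.stage_channels)) != 0:
        issues.append(f"phantom.edge {p.edge} not divisible by "
                      f"2^{len(config.cae.stage_channels)} (cae stages)")
    if p.edge % 16 != 0:
        issues.append(f"phantom.edge {p.edge} must be divisible by 16 "
                      f"(four encoder stages)")
    if not (0 <= p.anomaly_rate_unlabelled <= 1):
        issues.append("phantom.anomaly_rate_unlabelled outside [0, 1]")
    if config.ssl.warmup_epochs >= config.ssl.epochs:
        issues.append("ssl.warmup_epochs must be < ssl.epochs")
    if not (0 < config.finetune.label_fraction <= 1):
        issues.append("finetune.label_fraction outside (0, 1]")
    if config.residual.median_kernel is not None and \
            config.residual.median_kernel % 2 == 0:
        issues.append("residual.median_kernel must be odd or null")
    if config.k_folds < 2:
        issues.append("k_folds must be >= 2")
    if not (0 <= config.fold_index < config.k_folds):
        issues.append("fold_index outside [0, k_folds)")
    for init in config.finetune.inits:
        if init not in ("ssl_pretrained", "random_init"):
            issues.append(f"unknown finetune init {init!r}")
    if config.scale_profile not in ("desk", "full"):
        issues.append(f"unknown scale_profile {config.scale_profile!r}")
    return issues


def _hash_cfg(*parts) -> str:
    body = json.dumps(parts, sort_keys=True, default=str)
    return hashlib.sha1(body.encode()).hexdigest()[:16]


class _StageRunner:
    def __init__(self, out_dir: Path, log):
        self.out_dir = out_dir
        self.log = log
        self.manifest: dict = {"stages": {}}

    def run(self, name: str, cfg_hash: str, artifacts: list[Path], fn):
        status_path = self.out_dir / f"status_{name}.json"
        cached = False
        if status_path.exists():
            status = json.loads(status_path.read_text())
            if status.get("config_hash") == cfg_hash and \
                    all(a.exists() for a in artifacts):
                cached = True
        if cached:
            self.log(f"[{name}] cached")
        else:
            self.log(f"[{name}] running")
            try:
                fn()
            except Exception:
                self.log(f"[{name}] FAILED (partial artifacts preserved)")
                raise
            status_path.write_text(json.dumps(
                {"config_hash": cfg_hash, "artifacts": [str(a) for a in artifacts]},
                indent=1))
        self.manifest["stages"][name] = {
            "config_hash": cfg_hash, "cached": cached,
            "artifacts": [str(a) for a in artifacts]}
        return cached


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Execute all stages in order; returns the run manifest."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    log = log or (lambda msg: None)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(out, log)
    seeds = {name: stage_seed(config.root_seed, i) for i, name in enumerate(
        ("synth", "split", "cae", "residuals", "ssl", "finetune"), start=1)}

    # ----- stage 1: synth --------------------------------------------------
    p = config.phantom
    params = PhantomParams(cube_edge=p.edge)
    data_dir = out / "data"
    synth_hash = _hash_cfg("synth", asdict(p), seeds["synth"])
    runner.run("synth", synth_hash,
               [data_dir / "labelled.csv", data_dir / "unlabelled.csv"],
               lambda: generate_dataset(p.n_normal, p.n_anomalous, p.n_unlabelled,
                                        p.anomaly_rate_unlabelled,
                                        seed=seeds["synth"], params=params,
                                        out_dir=data_dir))
    labelled, unlabelled, hidden_masks = generate_dataset(
        p.n_normal, p.n_anomalous, p.n_unlabelled, p.anomaly_rate_unlabelled,
        seed=seeds["synth"], params=params)
    labelled_volumes = [s.volume for s in labelled]

    # ----- stage 2: split --------------------------------------------------
    split_hash = _hash_cfg("split", config.k_folds, config.fold_index,
                           synth_hash, seeds["split"])
    folds = make_cv_folds(labelled_volumes, k=config.k_folds, seed=seeds["split"])
    split = folds[config.fold_index]

    def write_split():
        rows = []
        for fold_idx, fs in enumerate(folds):
            for part, vols in (("train", fs.train), ("validation", fs.validation),
                               ("test", fs.test)):
                rows.extend({"fold": fold_idx, "partition": part, "uid": v.uid,
                             "patient_id": v.patient_id, "label": v.label}
                            for v in vols)
        pd.DataFrame(rows).to_csv(out / "splits.csv", index=False)
    runner.run("split", split_hash, [out / "splits.csv"], write_split)

    # ----- stage 3: CAE on the normal training subset ----------------------
    c = config.cae
    cae_cfg = CAEConfig(in_edge=p.edge, stage_channels=tuple(c.stage_channels),
                        latent_dim=c.latent_dim)
    cae_hash = _hash_cfg("cae", asdict(c), split_hash, seeds["cae"])
    cae_path = out / "cae.ckpt"

    def do_cae():
        state = build_cae(cae_cfg, seed=seeds["cae"])
        train_cae(state, split.normal_train_subset, loss=LossSpec(c.loss),
                  epochs=c.epochs, batch_size=c.batch_size, lr=c.lr,
                  seed=seeds["cae"])
        state.save(cae_path)
    runner.run("train_cae", cae_hash, [cae_path], do_cae)
    cae_state = load_model_state(cae_path)

    # ----- stage 4: residual volumes on the unlabelled pool ----------------
    r = config.residual
    res_hash = _hash_cfg("residuals", asdict(r), cae_hash)
    res_dir = out / "residuals"
    res_marker = res_dir / "residuals_done.json"

    def do_residuals():
        generate_residual_dataset(cae_state, unlabelled,
                                  median_kernel=r.median_kernel, out_dir=res_dir)
        res_marker.write_text(json.dumps({"count": len(unlabelled)}))
    runner.run("residuals", res_hash, [res_marker], do_residuals)
    residuals = generate_residual_dataset(cae_state, unlabelled,
                                          median_kernel=r.median_kernel)

    # ----- stage 5: SSL pretraining ----------------------------------------
    u, s = config.unet, config.ssl
    unet_cfg = UNetConfig(stage_channels=tuple(u.stage_channels),
                          width_factor=u.width_factor,
                          skip_connections=u.skip_connections)
    ssl_hash = _hash_cfg("ssl", asdict(u), asdict(s), res_hash, seeds["ssl"])
    enc_path = out / "encoder_ssl.ckpt"
    dec_path = out / "decoder_ssl.ckpt"

    def do_ssl():
        enc, dec = build_unet(unet_cfg, seed=seeds["ssl"])
        pcfg = PretrainConfig(loss=LossSpec(s.loss), epochs=s.epochs,
                              warmup_epochs=s.warmup_epochs, peak_lr=s.peak_lr,
                              batch_size=s.batch_size,
                              optimizer=s.optimizer,
                              augmentations=AugmentConfig(enabled=s.augment),
                              seed=seeds["ssl"])
        enc, dec = pretrain_reconstructor(enc, dec, list(zip(unlabelled, residuals)),
                                          pcfg)
        enc.save(enc_path)
        dec.save(dec_path)
        pd.DataFrame(enc.history[-1]["curve"]).to_csv(out / "ssl_log.csv",
                                                      index=False)
    runner.run("pretrain", ssl_hash, [enc_path, dec_path], do_ssl)

    # ----- stage 6: finetune + evaluate ------------------------------------
    f = config.finetune
    ft_hash = _hash_cfg("finetune", asdict(f), ssl_hash, seeds["finetune"])
    results_path = out / "results.csv"
    summary_path = out / "summary.json"

    def do_finetune():
        encoders = {}
        for init in f.inits:
            if init == "ssl_pretrained":
                encoders[init] = load_model_state(enc_path)
            else:
                enc_rand, _ = build_unet(unet_cfg, seed=seeds["finetune"])
                encoders[init] = enc_rand
        ft_cfg = FinetuneConfig(lr=f.lr, epochs=f.epochs, batch_size=f.batch_size,
                                hidden=f.hidden,
                                augmentations=AugmentConfig(enabled=f.augment))
        table, reports = run_learning_curve(
            encoders, [split], fractions=[f.label_fraction],
            seeds=[seeds["finetune"]], config=ft_cfg)
        table.to_csv(results_path, index=False, float_format="%.10f")
        summary = {f"{k[1]}@{k[0]}": v for k, v in reports.items()}
        summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    runner.run("finetune_eval", ft_hash, [results_path, summary_path], do_finetune)

    runner.manifest["root_seed"] = config.root_seed
    runner.manifest["stage_seeds"] = seeds
    runner.manifest["config_hash"] = _hash_cfg("run", asdict(config))
    runner.manifest["results"] = str(results_path)
    (out / "run_manifest.json").write_text(
        json.dumps(runner.manifest, indent=1, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return runner.manifest
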