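"""Architecture builders: convolutional autoencoder A(.), skip-connected
encoder-decoder (E, D) with a ResNet18-style 3D encoder, and the MLP
classification head.

Every builder is a pure function of (config, seed): the same seed yields
bit-identical initial parameters. Model states carry a provenance tag that
only moves forward along the pipeline
(random_init -> cae_trained -> ssl_pretrained -> finetuned).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (BatchNorm3d, Conv3d, GlobalAvgPool3d, LeakyReLU, Linear,
                 Module, ReLU, Sequential, Sigmoid, TrilinearUpsample,
                 load_checkpoint, save_checkpoint)

PROVENANCE_ORDER = ("random_init", "cae_trained", "ssl_pretrained", "finetuned")


@dataclass
class CAEConfig:
    in_edge: int = 64
    stage_channels: tuple[int, ...] = (16, 32, 64, 64)
    latent_dim: int = 512
    output_activation: str = "sigmoid"

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.in_edge % (2 ** len(self.stage_channels)) != 0:
            raise ValueError(
                f"in_edge {self.in_edge} not divisible by 2^{len(self.stage_channels)}")
        if self.output_activation not in ("sigmoid", "identity"):
            raise ValueError("output_activation must be 'sigmoid' or 'identity'")


@dataclass
class UNetConfig:
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    width_factor: float = 1.0
    skip_connections: bool = True
    upsampling: str = "trilinear"

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        if self.width_factor <= 0:
            raise ValueError("width_factor must be positive")
        if self.upsampling != "trilinear":
            raise ValueError("only trilinear upsampling is supported")

    @property
    def effective_channels(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(c * self.width_factor)))
                     for c in self.stage_channels)

    @property
    def feature_dim(self) -> int:
        return self.effective_channels[-1]


@dataclass
class ModelState:
    """Opaque trained-parameter container with provenance."""

    module: Module
    kind: str  # cae | encoder | decoder | classifier
    config: dict
    provenance: str = "random_init"
    seed: int = 0
    history: list = field(default_factory=list)

    def advance(self, provenance: str) -> None:
        if PROVENANCE_ORDER.index(provenance) < PROVENANCE_ORDER.index(self.provenance):
            raise ValueError(
                f"provenance may only move forward, not {self.provenance} -> {provenance}")
        self.provenance = provenance

    def save(self, path: Path | str) -> None:
        meta = {"kind": self.kind, "config": self.config,
                "provenance": self.provenance, "seed": self.seed,
                "history": self.history}
        save_checkpoint(path, self.module, meta)

    @property
    def fingerprint(self) -> str:
        body = json.dumps({"kind": self.kind, "config": self.config,
                           "provenance": self.provenance, "seed": self.seed},
                          sort_keys=True)
        return hashlib.sha1(body.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# CAE

class CAE3D(Module):
    """Strided conv encoder -> dense bottleneck -> upsample-conv decoder."""

    def __init__(self, config: CAEConfig, rng: np.random.Generator):
        ch = config.stage_channels
        self.config = config
        enc_layers: list[Module] = []
        cin = 1
        for c in ch:
            enc_layers += [Conv3d(cin, c, 3, stride=2, padding=1, rng=rng),
                           BatchNorm3d(c), LeakyReLU()]
            cin = c
        self.encoder = Sequential(*enc_layers)
        self._bottleneck_edge = config.in_edge // (2 ** len(ch))
        flat = ch[-1] * self._bottleneck_edge ** 3
        self.fc_in = Linear(flat, config.latent_dim, rng=rng)
        self.act_in = LeakyReLU()
        self.fc_out = Linear(config.latent_dim, flat, rng=rng)
        self.act_out = LeakyReLU()
        # decoder mirrors the encoder; the last stage is upsample followed by
        # the 1-channel output convolution
        dec_layers: list[Module] = []
        rev = list(ch[::-1])
        cin = ch[-1]
        for c in rev[1:]:
            dec_layers += [TrilinearUpsample(2),
                           Conv3d(cin, c, 3, stride=1, padding=1, rng=rng),
                           BatchNorm3d(c), LeakyReLU()]
            cin = c
        dec_layers += [TrilinearUpsample(2),
                       Conv3d(cin, 1, 3, stride=1, padding=1, rng=rng)]
        if config.output_activation == "sigmoid":
            dec_layers.append(Sigmoid())
        self.decoder = Sequential(*dec_layers)

    def forward(self, x, training=False):
        h = self.encoder.forward(x, training=training)
        self._h_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        z = self.act_in.forward(self.fc_in.forward(flat, training), training)
        g = self.act_out.forward(self.fc_out.forward(z, training), training)
        h2 = g.reshape(self._h_shape)
        return self.decoder.forward(h2, training=training)

    def backward(self, gout):
        g = self.decoder.backward(gout)
        g = g.reshape(g.shape[0], -1)
        g = self.fc_out.backward(self.act_out.backward(g))
        g = self.fc_in.backward(self.act_in.backward(g))
        g = g.reshape(self._h_shape)
        return self.encoder.backward(g)


def build_cae(config: CAEConfig, seed: int) -> ModelState:
    rng = np.random.default_rng(seed)
    return ModelState(module=CAE3D(config, rng), kind="cae",
                      config=asdict(config), seed=seed)


# ---------------------------------------------------------------------------
# ResNet18-3D encoder

class BasicBlock3d(Module):
    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv3d(cin, cout, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm3d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm3d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.proj = Conv3d(cin, cout, 1, stride=stride, padding=0, rng=rng)
            self.proj_bn = BatchNorm3d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x, training=False):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training),
                                                  training), training)
        out = self.bn2.forward(self.conv2.forward(out, training), training)
        short = x if self.proj is None else self.proj_bn.forward(
            self.proj.forward(x, training), training)
        return self.relu2.forward(out + short, training)

    def backward(self, gout):
        g = self.relu2.backward(gout)
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        if self.proj is None:
            g_short = g
        else:
            g_short = self.proj.backward(self.proj_bn.backward(g))
        return g_main + g_short


class ResNetEncoder3d(Module):
    """Four downsampling stages of basic blocks over a stride-1 stem.

    ``forward_map`` exposes the stage feature maps for decoder skips;
    ``forward`` pools the deepest map into the feature vector used by the
    classifier head.
    """

    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        ch = config.effective_channels
        self.config = config
        self.stem = Sequential(Conv3d(1, ch[0], 3, stride=1, padding=1, rng=rng),
                               BatchNorm3d(ch[0]), ReLU())
        self.stages = []
        cin = ch[0]
        for c in ch:
            self.stages.append(Sequential(BasicBlock3d(cin, c, 2, rng),
                                          BasicBlock3d(c, c, 1, rng)))
            cin = c
        self.pool = GlobalAvgPool3d()

    def forward_map(self, x, training=False):
        f = self.stem.forward(x, training=training)
        skips = [f]
        for stage in self.stages:
            f = stage.forward(f, training=training)
            skips.append(f)
        bottleneck = skips.pop()
        return bottleneck, skips

    def backward_map(self, g_bottleneck, g_skips=None):
        g = g_bottleneck
        for i in range(len(self.stages) - 1, -1, -1):
            g = self.stages[i].backward(g)
            if g_skips is not None and i > 0:
                g = g + g_skips[i]
        if g_skips is not None:
            g = g + g_skips[0]
        return self.stem.backward(g)

    def forward(self, x, training=False):
        bottleneck, _ = self.forward_map(x, training=training)
        return self.pool.forward(bottleneck, training=training)

    def backward(self, gout):
        return self.backward_map(self.pool.backward(gout))


class UNetDecoder3d(Module):
    """Mirrors the encoder with trilinear upsampling and optional skips."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        ch = config.effective_channels
        self.config = config
        self.skip_connections = config.skip_connections
        # decoder stage i upsamples then convolves concat(up, skip) down to the
        # next-shallower channel count; skip channels are (ch[0], ch[0..2])
        skip_ch = [ch[0]] + list(ch[:-1])
        self.ups = []
        self.convs = []
        cin = ch[-1]
        for i in range(len(ch) - 1, -1, -1):
            target = skip_ch[i]
            self.ups.append(TrilinearUpsample(2))
            conv_in = cin + (skip_ch[i] if self.skip_connections else 0)
            self.convs.append(Sequential(
                Conv3d(conv_in, target, 3, stride=1, padding=1, rng=rng),
                BatchNorm3d(target), LeakyReLU()))
            cin = target
        self.head = Sequential(Conv3d(cin, 1, 3, stride=1, padding=1, rng=rng),
                               Sigmoid())

    def forward(self, bottleneck, skips, training=False):
        # skips: [stem, stage1, ..., stage_{S-1}] shallow -> deep
        f = bottleneck
        self._split_channels = []
        for idx, (up, conv) in enumerate(zip(self.ups, self.convs)):
            f = up.forward(f, training=training)
            if self.skip_connections:
                skip = skips[len(skips) - 1 - idx]
                self._split_channels.append(f.shape[1])
                f = np.concatenate([f, skip], axis=1)
            f = conv.forward(f, training=training)
        return self.head.forward(f, training=training)

    def backward(self, gout):
        g = self.head.backward(gout)
        g_skips = [None] * (len(self.convs))
        for idx in range(len(self.convs) - 1, -1, -1):
            g = self.convs[idx].backward(g)
            if self.skip_connections:
                c_up = self._split_channels[idx]
                g_skip = g[:, c_up:]
                g = g[:, :c_up]
                g_skips[len(g_skips) - 1 - idx] = g_skip
            g = self.ups[idx].backward(g)
        if not self.skip_connections:
            g_skips = None
        return g, g_skips


def build_unet(config: UNetConfig, seed: int) -> tuple[ModelState, ModelState]:
    rng = np.random.default_rng(seed)
    encoder = ResNetEncoder3d(config, rng)
    decoder = UNetDecoder3d(config, rng)
    cfg = asdict(config)
    return (ModelState(module=encoder, kind="encoder", config=cfg, seed=seed),
            ModelState(module=decoder, kind="decoder", config=cfg, seed=seed))


# ---------------------------------------------------------------------------
# classifier

class Classifier3d(Module):
    """Encoder + global average pooling + MLP(feature -> hidden -> n_classes)."""

    def __init__(self, encoder: ResNetEncoder3d, hidden: int, n_classes: int,
                 rng: np.random.Generator):
        self.encoder = encoder
        feat = encoder.config.feature_dim
        self.fc1 = Linear(feat, hidden, rng=rng)
        self.act = ReLU()
        self.fc2 = Linear(hidden, n_classes, rng=rng)

    def features(self, x, training=False):
        return self.encoder.forward(x, training=training)

    def forward(self, x, training=False):
        f = self.encoder.forward(x, training=training)
        return self.fc2.forward(self.act.forward(self.fc1.forward(f, training),
                                                 training), training)

    def backward(self, gout):
        g = self.fc1.backward(self.act.backward(self.fc2.backward(gout)))
        return self.encoder.backward(g)


def build_classifier(encoder: ModelState, hidden: int = 256, n_classes: int = 2,
                     seed: int = 0) -> ModelState:
    if encoder.provenance not in ("random_init", "ssl_pretrained"):
        raise ValueError(
            f"classifier must start from random_init or ssl_pretrained encoder, "
            f"got {encoder.provenance}")
    rng = np.random.default_rng(seed)
    enc_module = copy.deepcopy(encoder.module)
    module = Classifier3d(enc_module, hidden=hidden, n_classes=n_classes, rng=rng)
    cfg = {"encoder": encoder.config, "hidden": hidden, "n_classes": n_classes,
           "encoder_provenance": encoder.provenance}
    return ModelState(module=module, kind="classifier", config=cfg,
                      provenance=encoder.provenance, seed=seed)


# ---------------------------------------------------------------------------
# checkpoint round-trip

def load_model_state(path: Path | str) -> ModelState:
    meta, arrays = load_checkpoint(path)
    kind, cfg = meta["kind"], meta["config"]
    if kind == "cae":
        state = build_cae(CAEConfig(**{k: v for k, v in cfg.items()}), meta["seed"])
    elif kind == "encoder":
        state, _ = build_unet(UNetConfig(**cfg), meta["seed"])
    elif kind == "decoder":
        _, state = build_unet(UNetConfig(**cfg), meta["seed"])
    elif kind == "classifier":
        enc_state, _ = build_unet(UNetConfig(**cfg["encoder"]), meta["seed"])
        rng = np.random.default_rng(meta["seed"])
        module = Classifier3d(enc_state.module, hidden=cfg["hidden"],
                              n_classes=cfg["n_classes"], rng=rng)
        state = ModelState(module=module, kind="classifier", config=cfg,
                           seed=meta["seed"])
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    state.module.load_state_arrays(arrays)
    state.provenance = meta["provenance"]
    state.history = meta.get("history", [])
    return state
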