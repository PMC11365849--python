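"""Minimal layer/module machinery for the 3D networks in this package.

Layers cache what their backward pass needs during ``forward`` and release it
after ``backward``; a module is therefore not re-entrant across interleaved
forward calls. Training is deterministic for a fixed seed.
"""

from __future__ import annotations

import io
import json
import zipfile
from typing import Iterator

import numpy as np

#: Default parameter/activation dtype. float32 keeps the memory-bound conv
#: passes fast; switch to float64 (before building a model) for
#: finite-difference gradient checks.
DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name}, shape={self.data.shape})"


class Module:
    """Base class: subclasses implement forward(x, training) and backward(gout)."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for child in self.children():
            out.extend(child.parameters())
        for value in vars(self).values():
            if isinstance(value, Parameter):
                out.append(value)
        return out

    def children(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    # -- state (running stats live alongside parameters) --------------------
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for key, value in vars(self).items():
            path = f"{prefix}{key}"
            if isinstance(value, Parameter):
                out[path] = value.data
            elif isinstance(value, Module):
                out.update(value.state_arrays(prefix=path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{path}.{i}."))
            elif isinstance(value, np.ndarray) and key.startswith("running_"):
                out[path] = value
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for key, value in vars(self).items():
            path = f"{prefix}{key}"
            if isinstance(value, Parameter):
                value.data = np.array(arrays[path], dtype=DTYPE)
                value.grad = np.zeros_like(value.data)
            elif isinstance(value, Module):
                value.load_state_arrays(arrays, prefix=path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, prefix=f"{path}.{i}.")
            elif isinstance(value, np.ndarray) and key.startswith("running_"):
                setattr(self, key, np.array(arrays[path], dtype=DTYPE))

    def checksum(self) -> float:
        """Order-stable scalar fingerprint of all parameters."""
        arrays = self.state_arrays()
        return float(sum(np.sum(arrays[name]) for name in sorted(arrays)))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


CHECKPOINT_FORMAT_VERSION = 1


def save_checkpoint(path, module: Module, meta: dict) -> None:
    """Single-file checkpoint: zip of a JSON header plus raw ``.npy`` arrays."""
    arrays = module.state_arrays()
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "meta": meta,
        "arrays": sorted(arrays),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1, sort_keys=True))
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, arrays[name])
            zf.writestr(f"arrays/{name}.npy", buf.getvalue())


def load_checkpoint(path) -> tuple[dict, dict[str, np.ndarray]]:
    with zipfile.ZipFile(path, "r") as zf:
        header = json.loads(zf.read("header.json"))
        if header["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {header['format_version']}")
        arrays = {}
        for name in header["arrays"]:
            arrays[name] = np.load(io.BytesIO(zf.read(f"arrays/{name}.npy")))
    return header["meta"], arrays
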