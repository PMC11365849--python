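"""Optimizers over :class:`~sinussl.nn.core.Parameter` lists.

AdamW follows the decoupled weight-decay formulation; LARS applies a
layerwise trust ratio on top of SGD with momentum, as used for large-batch
self-supervised pretraining. All optimizers accept the learning rate at
``step`` time so external schedules stay in one place.
"""

from __future__ import annotations

import numpy as np

from .core import Parameter


class Optimizer:
    def __init__(self, params: list[Parameter]):
        self.params = params

    def step(self, lr: float) -> None:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD(Optimizer):
    def __init__(self, params, momentum: float = 0.9, weight_decay: float = 0.0):
        super().__init__(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v


class Adam(Optimizer):
    def __init__(self, params, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decoupled: bool = False):
        super().__init__(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self, lr: float) -> None:
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and self.decoupled:
                update = update + self.weight_decay * p.data
            p.data -= lr * update


class AdamW(Adam):
    def __init__(self, params, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        super().__init__(params, betas=betas, eps=eps,
                         weight_decay=weight_decay, decoupled=True)


class LARS(Optimizer):
    """Layerwise adaptive rate scaling on top of SGD momentum.

    Each parameter's step is rescaled by trust_coeff * ||w|| / ||g||, which
    stabilizes very large batch sizes; biases and norm parameters (ndim <= 1)
    are excluded from the adaptation, following common practice.
    """

    def __init__(self, params, momentum: float = 0.9, weight_decay: float = 0.0,
                 trust_coeff: float = 1e-3, eps: float = 1e-12):
        super().__init__(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.trust_coeff = trust_coeff
        self.eps = eps
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad + self.weight_decay * p.data
            if p.data.ndim > 1:
                w_norm = np.linalg.norm(p.data)
                g_norm = np.linalg.norm(g)
                if w_norm > 0 and g_norm > 0:
                    g = g * (self.trust_coeff * w_norm / (g_norm + self.eps))
            v *= self.momentum
            v += g
            p.data -= lr * v


OPTIMIZERS = {"sgd": SGD, "adam": Adam, "adamw": AdamW, "lars": LARS}


def make_optimizer(name: str, params, **kwargs) -> Optimizer:
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    return cls(params, **kwargs)
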