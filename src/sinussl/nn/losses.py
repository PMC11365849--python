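"""Reconstruction and classification losses.

Each function returns ``(loss, grad)`` where ``grad`` is the derivative of the
mean loss with respect to the prediction array. Reconstruction losses operate
on probabilities (the decoders end in a sigmoid), so BCE clamps its input away
from {0, 1} before taking logs.
"""

from __future__ import annotations

import numpy as np

_BCE_EPS = 1e-7


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def l2_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def bce_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    if np.any(target < 0) or np.any(target > 1):
        raise ValueError("BCE targets must lie in [0, 1]")
    p = np.clip(pred, _BCE_EPS, 1.0 - _BCE_EPS)
    loss = -np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))
    grad = (p - target) / (p * (1.0 - p)) / p.size
    # no gradient through the clamp
    grad[(pred <= _BCE_EPS) & (target >= pred)] = np.minimum(
        grad[(pred <= _BCE_EPS) & (target >= pred)], 0.0)
    return float(loss), grad


RECON_LOSSES = {"L1": l1_loss, "L2": l2_loss, "BCE": bce_loss}


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``labels`` under a softmax over ``logits``.

    For the two-class head this is the multi-class form of binary
    cross-entropy on the anomalous-class probability.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
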