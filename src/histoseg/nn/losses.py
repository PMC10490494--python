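"""Losses: mean squared reconstruction error and pixel-wise softmax cross-entropy."""

from __future__ import annotations

import numpy as np


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dL/dpred)."""
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff**2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-pixel cross-entropy of channel softmax against integer labels.

    ``logits``: (B, K, H, W); ``labels``: (B, H, W) ints in [0, K).
    Returns the mean loss over pixels and dL/dlogits. The softmax is
    stabilized by subtracting the per-pixel max, to which it is invariant.
    """
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    b, k, h, w = logits.shape
    onehot = np.moveaxis(np.eye(k, dtype=np.float32)[labels], -1, 1)
    n_pix = b * h * w
    log_probs = shifted - np.log(exp.sum(axis=1, keepdims=True))
    loss = float(-(onehot * log_probs).sum() / n_pix)
    grad = (probs - onehot) / n_pix
    return loss, grad.astype(np.float32)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Stable channel softmax of (B, K, H, W) logits."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=1, keepdims=True)
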