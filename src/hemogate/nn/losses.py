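"""Loss functions returning (scalar loss, gradient w.r.t. logits)."""

from __future__ import annotations

import numpy as np

from .functional import sigmoid


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Numerically stable binary cross-entropy on raw logits (mean over batch)."""
    z = logits.astype(np.float64).ravel()
    t = targets.astype(np.float64).ravel()
    # log(1+exp(-|z|)) + max(z,0) - z*t
    loss = np.mean(np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * t)
    grad = (sigmoid(z) - t) / z.size
    return float(loss), grad.reshape(logits.shape).astype(np.float32)


def soft_dice_with_logits(logits: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Soft Dice loss (squared-denominator variant), mean over batch.

    ``dice = (2 Σ p·t + eps) / (Σ p² + Σ t² + eps)``; the squared denominator
    keeps background gradients proportional to p, which prevents the
    collapse-to-empty failure mode on small foregrounds. Logits/targets are
    (N,1,D,H,W).
    """
    p = sigmoid(logits.astype(np.float64))
    n = logits.shape[0]
    pf = p.reshape(n, -1)
    tf = targets.reshape(n, -1).astype(np.float64)
    inter = (pf * tf).sum(axis=1)
    denom = (pf**2).sum(axis=1) + (tf**2).sum(axis=1) + eps
    num = 2.0 * inter + eps
    loss = float(np.mean(1.0 - num / denom))
    # d(1-dice)/dp = -(2 t * denom - num * 2 p) / denom^2
    ddice_dp = (2.0 * tf * denom[:, None] - num[:, None] * 2.0 * pf) / denom[:, None] ** 2
    grad = -ddice_dp * pf * (1.0 - pf) / n
    return loss, grad.reshape(logits.shape).astype(np.float32)
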