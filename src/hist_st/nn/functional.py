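"""Loss functions with numerically stable, hand-derived gradients."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["mse_loss", "bce_with_logits", "cross_entropy_logits"]


def mse_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    t = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=pred.data.dtype)
    diff = pred - Tensor(t)
    return (diff * diff).mean()


def bce_with_logits(logits: Tensor, target: np.ndarray | Tensor) -> Tensor:
    """Mean binary cross-entropy from raw logits (log-sum-exp stable)."""
    t = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=logits.data.dtype)
    z = logits.data
    # softplus(z) - t*z  ==  max(z,0) - t*z + log1p(exp(-|z|))
    loss = np.maximum(z, 0.0) - t * z + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def bw(g):
        from scipy.special import expit
        logits._accum(g * (expit(z) - t) / n)

    return Tensor._result(np.array(loss.mean(), dtype=z.dtype), (logits,), bw)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over classes from a (batch, classes) logit tensor."""
    z = logits.data
    labels = np.asarray(labels, dtype=np.int64)
    zmax = z.max(axis=1, keepdims=True)
    logp = z - zmax - np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p / n)

    return Tensor._result(np.array(loss, dtype=z.dtype), (logits,), bw)
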