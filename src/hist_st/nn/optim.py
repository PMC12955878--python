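"""Optimizers and learning-rate schedules (Adam, AdamW, cosine annealing)."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "AdamW", "CosineAnnealingLR"]


class _AdamBase:
    def __init__(self, params: list[Parameter], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self._update(p, g, i, bc1, bc2)

    def _update(self, p, g, i, bc1, bc2):
        raise NotImplementedError


class Adam(_AdamBase):
    """Adam with L2 regularization folded into the gradient (coupled decay)."""

    def _update(self, p, g, i, bc1, bc2):
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        b1, b2 = self.betas
        self.m[i] = b1 * self.m[i] + (1 - b1) * g
        self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
        p.data = p.data - self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


class AdamW(_AdamBase):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        super().__init__(params, lr, betas, eps, weight_decay)

    def _update(self, p, g, i, bc1, bc2):
        b1, b2 = self.betas
        self.m[i] = b1 * self.m[i] + (1 - b1) * g
        self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
        p.data = p.data - self.lr * (
            (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            + self.weight_decay * p.data)


class CosineAnnealingLR:
    """Cosine decay of the learning rate from lr0 to eta_min over t_max epochs."""

    def __init__(self, optimizer: _AdamBase, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.lr0 = optimizer.lr
        self.t_max = t_max
        self.eta_min = eta_min
        self.epoch = 0

    def step(self):
        self.epoch += 1
        frac = min(self.epoch, self.t_max) / self.t_max
        self.optimizer.lr = self.eta_min + 0.5 * (self.lr0 - self.eta_min) * (
            1.0 + math.cos(math.pi * frac))
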