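"""Adam optimizer and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, params, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving.

    "Plateau" means no improvement greater than ``threshold`` for
    ``patience`` consecutive epochs; the rate never drops below ``min_lr``.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-5, threshold: float = 1e-4):
        self.optimizer = optimizer
        self.factor, self.patience = factor, patience
        self.min_lr, self.threshold = min_lr, threshold
        self.best = np.inf
        self.stale = 0

    def step(self, loss: float) -> bool:
        """Feed one epoch's monitored loss; returns True if the LR dropped."""
        if loss < self.best - self.threshold:
            self.best = loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.stale = 0
            new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
            changed = new_lr < self.optimizer.lr
            self.optimizer.lr = new_lr
            return changed
        return False
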