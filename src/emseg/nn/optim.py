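"""Adam optimizer and reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .graph import Param

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
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
            p.value = (p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                       ).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when the monitored loss has
    not improved for ``patience`` consecutive epochs; never below ``min_lr``."""

    def __init__(self, optimizer: Adam, factor: float = 0.25, patience: int = 10,
                 min_lr: float = 1e-7):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must lie in (0, 1)")
        self.opt = optimizer
        self.factor = factor
        self.patience = int(patience)
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    def step(self, loss: float) -> float:
        """Record one epoch's monitored loss; return the (possibly reduced) lr."""
        if loss < self.best - 1e-12:
            self.best = loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.wait = 0
        return self.opt.lr
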