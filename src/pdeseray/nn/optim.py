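"""Optimisers and learning-rate scheduling used by the training loop."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params: list[Parameter] = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 3,
                 min_lr: float = 1e-6, threshold: float = 1e-4):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> None:
        if value < self.best - self.threshold:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
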