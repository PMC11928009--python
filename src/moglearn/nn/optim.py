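"""Adam optimizer and validation-accuracy-driven LR scheduling."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, parameters, lr: float = 0.001, betas=(0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.parameters = list(parameters)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.parameters]
        self.v = [np.zeros_like(p.value) for p in self.parameters]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.parameters):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` when the monitored metric stops improving.

    ``mode='max'`` monitors validation accuracy (higher is better).
    """

    def __init__(
        self,
        optimizer: Adam,
        mode: str = "max",
        factor: float = 0.5,
        patience: int = 10,
        min_lr: float = 1e-6,
    ):
        if not 0 < factor < 1:
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.sign = 1.0 if mode == "max" else -1.0
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if self.sign * metric > self.best:
            self.best = self.sign * metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
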