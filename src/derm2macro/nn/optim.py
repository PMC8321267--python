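"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "CyclicLR"]


class Adam:
    """Adam with bias-corrected first/second moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class CyclicLR:
    """Triangular cyclic learning rate oscillating between two bounds.

    The rate rises linearly from ``base_lr`` to ``max_lr`` over
    ``step_size`` scheduler steps, then falls back symmetrically.
    """

    def __init__(self, optimizer: Adam, base_lr: float = 1e-5,
                 max_lr: float = 1e-3, step_size: int = 4):
        if max_lr < base_lr:
            raise ValueError("max_lr must be >= base_lr")
        if step_size < 1:
            raise ValueError("step_size must be positive")
        self.optimizer = optimizer
        self.base_lr = base_lr
        self.max_lr = max_lr
        self.step_size = step_size
        self.iteration = 0
        optimizer.lr = self.current_lr()

    def current_lr(self) -> float:
        cycle_pos = self.iteration % (2 * self.step_size)
        frac = cycle_pos / self.step_size
        if frac > 1.0:
            frac = 2.0 - frac
        return self.base_lr + (self.max_lr - self.base_lr) * frac

    def step(self) -> float:
        self.iteration += 1
        lr = self.current_lr()
        self.optimizer.lr = lr
        return lr
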