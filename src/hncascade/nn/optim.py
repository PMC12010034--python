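"""Optimizers and learning-rate schedules.

AdamW applies decoupled weight decay (decay directly on the weights, not
through the gradient moments). The cyclic schedule is the triangular
policy: the learning rate ramps linearly from ``base_lr`` to ``max_lr``
over half a cycle and back down over the other half.
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    def __init__(self, params: list[Parameter], lr: float = 3e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                         + self.weight_decay * p.data)


class CyclicLR:
    """Triangular cyclic learning rate, stepped once per epoch."""

    def __init__(self, optimizer: AdamW, base_lr: float, max_lr: float,
                 cycle_epochs: int = 20):
        if cycle_epochs < 2:
            raise ValueError("cycle_epochs must be >= 2")
        self.opt = optimizer
        self.base_lr = base_lr
        self.max_lr = max_lr
        self.cycle_epochs = cycle_epochs
        self.set_epoch(0)

    def lr_at(self, epoch: int) -> float:
        half = self.cycle_epochs / 2.0
        pos = epoch % self.cycle_epochs
        frac = pos / half if pos <= half else (self.cycle_epochs - pos) / half
        return self.base_lr + (self.max_lr - self.base_lr) * frac

    def set_epoch(self, epoch: int) -> None:
        self.opt.lr = self.lr_at(epoch)
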