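"""Adam, global-norm gradient clipping, and a triangular cyclic LR."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "clip_grad_norm", "CyclicLR"]


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most *max_norm*.

    Returns the pre-clip norm.
    """
    total = 0.0
    for p in params:
        total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            p.grad *= scale
    return norm


class CyclicLR:
    """Triangular cyclic learning rate over optimizer iterations."""

    def __init__(self, base_lr: float, max_lr: float, step_size: int):
        if step_size < 1:
            raise ValueError("step_size must be >= 1")
        self.base_lr, self.max_lr, self.step_size = base_lr, max_lr, step_size

    def lr(self, iteration: int) -> float:
        cycle_pos = (iteration % (2 * self.step_size)) / self.step_size
        frac = cycle_pos if cycle_pos <= 1.0 else 2.0 - cycle_pos
        return self.base_lr + (self.max_lr - self.base_lr) * frac
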