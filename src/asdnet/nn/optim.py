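"""Adam optimizer with L2 weight decay and a cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Parameter


class Adam:
    """Adaptive moment estimation.

    ``weight_decay`` is classic L2 regularisation (added to the gradient
    before the moment updates).
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(epoch: int, epochs: int, initial_lr: float, min_lr: float) -> float:
    """Cosine decay from ``initial_lr`` (epoch 0) to ``min_lr`` (final epoch)."""
    if epochs <= 1:
        return initial_lr
    t = epoch / (epochs - 1)
    return min_lr + 0.5 * (initial_lr - min_lr) * (1 + math.cos(math.pi * t))
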