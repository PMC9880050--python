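"""Adam optimizer with classic L2 weight decay (decay added to the
gradient, i.e. global L2 regularization of the weights)."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    def __init__(self, params: list[Parameter], learning_rate: float = 5e-5,
                 beta1: float = 0.9, beta2: float = 0.999,
                 epsilon: float = 1e-6, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = learning_rate
        self.beta1, self.beta2 = beta1, beta2
        self.eps = epsilon
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.value -= update.astype(p.value.dtype)
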