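"""Adaptive-moment (Adam) optimizer over Parameter objects."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    def __init__(
        self,
        parameters: list[Parameter],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        l2_coefficient: float = 0.0,
    ):
        self.parameters = parameters
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.l2 = l2_coefficient
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in parameters]
        self._v = [np.zeros_like(p.data) for p in parameters]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.parameters, self._m, self._v):
            grad = p.grad
            if self.l2 > 0.0 and p.regularizable:
                grad = grad + 2.0 * self.l2 * p.data
            m *= self.beta1
            m += (1.0 - self.beta1) * grad
            v *= self.beta2
            v += (1.0 - self.beta2) * grad * grad
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
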