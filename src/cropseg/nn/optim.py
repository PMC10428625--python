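"""Adam optimizer for Param objects."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p in self.params:
            st = p.state
            if "m" not in st:
                st["m"] = np.zeros_like(p.value)
                st["v"] = np.zeros_like(p.value)
            st["m"] = b1 * st["m"] + (1 - b1) * p.grad
            st["v"] = b2 * st["v"] + (1 - b2) * p.grad**2
            mhat = st["m"] / bias1
            vhat = st["v"] / bias2
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
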