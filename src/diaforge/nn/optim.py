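"""Adam with linear learning-rate warmup (constant afterwards)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr_scale: float = 1.0) -> None:
        b1, b2 = self.betas
        self.t += 1
        lr = self.lr * lr_scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)


def warmup_scale(epoch: int, warmup_epochs: int) -> float:
    """Linear ramp from 1/warmup to 1 over the first ``warmup_epochs`` epochs."""
    if warmup_epochs <= 0 or epoch >= warmup_epochs:
        return 1.0
    return (epoch + 1) / warmup_epochs
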