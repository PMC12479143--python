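"""Adam optimiser and the step learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "step_lr"]


def step_lr(base_lr: float, epoch: int, factor: float = 0.2, every: int = 100) -> float:
    """Learning rate for 1-based ``epoch``: reduced by ``factor`` every ``every`` epochs.

    Epochs 1..every use ``base_lr``, epochs every+1..2*every use
    ``base_lr * factor``, and so on.
    """
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    return base_lr * factor ** ((epoch - 1) // every)


class Adam:
    """Adaptive-moment estimation over a fixed parameter list."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
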