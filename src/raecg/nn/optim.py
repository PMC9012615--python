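"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "StepLR"]


class Adam:
    """Adam with bias correction (Kingma & Ba defaults)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class StepLR:
    """Multiply the learning rate by `gamma` every `step_epochs` epochs.

    `lr_at(epoch)` is 1-based: epochs 1..step_epochs use the initial rate.
    """

    def __init__(self, optimizer: Adam | None, initial_lr: float,
                 step_epochs: int = 20, gamma: float = 0.1):
        self.optimizer = optimizer
        self.initial_lr = initial_lr
        self.step_epochs = step_epochs
        self.gamma = gamma

    def lr_at(self, epoch: int) -> float:
        if epoch < 1:
            raise ValueError("epochs are 1-based")
        return self.initial_lr * self.gamma ** ((epoch - 1) // self.step_epochs)

    def set_epoch(self, epoch: int) -> float:
        lr = self.lr_at(epoch)
        if self.optimizer is not None:
            self.optimizer.lr = lr
        return lr
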