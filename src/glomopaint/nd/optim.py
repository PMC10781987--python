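"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "CosineAnnealingLR"]


class Adam:
    """Adam with the conventional bias correction.

    Defaults follow the GAN training recipes used in this package
    (lr 1e-4, betas (0.5, 0.999)); callers override per model.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m) for m in state["m"]]
        self.v = [np.asarray(v) for v in state["v"]]


class CosineAnnealingLR:
    """Cosine decay of the optimiser learning rate from lr_max to lr_min."""

    def __init__(self, optimizer: Adam, t_max: int, lr_min: float = 1e-5):
        self.opt = optimizer
        self.t_max = max(1, t_max)
        self.lr_max = optimizer.lr
        self.lr_min = lr_min
        self.epoch = 0

    def step(self) -> float:
        self.epoch += 1
        t = min(self.epoch, self.t_max)
        lr = self.lr_min + 0.5 * (self.lr_max - self.lr_min) * (
            1.0 + math.cos(math.pi * t / self.t_max)
        )
        self.opt.lr = lr
        return lr
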