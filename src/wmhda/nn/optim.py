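"""Optimisers: Adam (main segmentation path) and momentum SGD (DANN domain head)."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["Optimizer", "Adam", "SGD"]


class Optimizer:
    def __init__(self, params: list[Parameter], lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-4):
        super().__init__(params, lr)
        self.betas = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self._t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None or not p.requires_grad:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


class SGD(Optimizer):
    def __init__(self, params, lr: float = 1e-3, momentum: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self._buf = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None or not p.requires_grad:
                continue
            buf *= self.momentum
            buf += p.grad
            p.data = p.data - (self.lr * buf).astype(p.data.dtype)
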