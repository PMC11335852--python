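"""Stochastic optimizers for the autodiff parameters.

NAdam (Adam with Nesterov momentum, Dozat 2016) is the default for
grounding runs; plain Adam and SGD are available for experiments. The
update rules follow the standard published formulas; all state lives in
per-parameter numpy arrays so optimizer state can be snapshotted along
with the model.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor


class Optimizer:
    def __init__(self, params: Sequence[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam(Optimizer):
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            p.data -= self.lr * self._direction(i, g, m_hat) / (np.sqrt(v_hat) + self.eps)

    def _direction(self, i: int, g: np.ndarray, m_hat: np.ndarray) -> np.ndarray:
        return m_hat


class NAdam(Adam):
    """Adam with a Nesterov look-ahead on the first moment."""

    def _direction(self, i: int, g: np.ndarray, m_hat: np.ndarray) -> np.ndarray:
        b1 = self.beta1
        return b1 * m_hat + (1 - b1) * g / (1 - b1**self.t)


def make_optimizer(kind: str, params: Sequence[Tensor], lr: float) -> Optimizer:
    kinds = {"sgd": SGD, "adam": Adam, "nadam": NAdam}
    try:
        cls = kinds[kind.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer kind {kind!r}; choose from {sorted(kinds)}")
    return cls(params, lr=lr)
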