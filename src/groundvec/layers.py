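"""Neural building blocks for the caption encoders and the concreteness MLP.

All modules are built on :mod:`groundvec.autodiff`. Parameters use a
seeded Glorot-uniform fan-based initialization so that identical seeds
give bitwise-identical models. Four sequence encoders are provided:

* :class:`BoWEncoder` — mean of the grounded token vectors, a tanh
  hidden layer, then a linear projection to the image space; order
  invariant by construction.
* :class:`LSTMEncoder` / :class:`GRUEncoder` — single- or multi-layer
  recurrent encoders whose final hidden state summarizes the caption;
  order sensitive.
* :class:`TransformerEncoder` — stacked self-attention blocks with
  sinusoidal position encodings, mean-pooled and linearly projected.
"""
from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .autodiff import Tensor, stack
from .errors import EmptyInputError

Array = np.ndarray


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int | None = None, fan_out: int | None = None) -> Array:
    fan_in = fan_in if fan_in is not None else shape[0]
    fan_out = fan_out if fan_out is not None else shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[Array]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[Array]) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = a.copy()

    train_mode: bool = True

    def set_training(self, flag: bool) -> None:
        self.train_mode = flag
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)


def _param(rng: np.random.Generator, shape: tuple[int, ...], **kw) -> Tensor:
    t = Tensor(glorot_uniform(rng, shape, **kw))
    t.requires_grad = True
    return t


def _zeros(shape: tuple[int, ...]) -> Tensor:
    t = Tensor(np.zeros(shape))
    t.requires_grad = True
    return t


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 bias: bool = True):
        self.W = _param(rng, (n_in, n_out))
        self.b = _zeros((n_out,)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class LSTMEncoder(Module):
    """Stacked LSTM; returns the final time-step's top-layer hidden state.

    Initial hidden/cell states default to zeros (deterministic); with
    ``learned_init`` they become trainable parameters shared across
    sequences.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, units: int,
                 layers: int = 1, learned_init: bool = False):
        self.units = units
        self.cells: list[Module] = []
        for layer in range(layers):
            cell = Module()
            d = n_in if layer == 0 else units
            cell.W = _param(rng, (d, 4 * units), fan_in=d, fan_out=units)
            cell.U = _param(rng, (units, 4 * units), fan_in=units, fan_out=units)
            cell.b = _zeros((4 * units,))
            cell.h0 = _zeros((units,)) if learned_init else Tensor(np.zeros(units))
            cell.c0 = _zeros((units,)) if learned_init else Tensor(np.zeros(units))
            self.cells.append(cell)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (batch, n, d) -> (batch, units)."""
        if x.shape[1] == 0:
            raise EmptyInputError("cannot encode an empty token sequence")
        batch, n, _ = x.shape
        H = self.units
        seq = x
        for cell in self.cells:
            ones = Tensor(np.ones((batch, 1)))
            h = ones @ cell.h0.reshape(1, H)
            c = ones @ cell.c0.reshape(1, H)
            outputs = []
            for t in range(n):
                gates = seq[:, t, :] @ cell.W + h @ cell.U + cell.b
                i = gates[:, :H].sigmoid()
                f = gates[:, H:2 * H].sigmoid()
                g = gates[:, 2 * H:3 * H].tanh()
                o = gates[:, 3 * H:].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outputs.append(h)
            seq = stack(outputs, axis=1)
        return h


class GRUEncoder(Module):
    """Stacked GRU; only a hidden state, no cell state."""

    def __init__(self, rng: np.random.Generator, n_in: int, units: int,
                 layers: int = 1, learned_init: bool = False):
        self.units = units
        self.cells: list[Module] = []
        for layer in range(layers):
            cell = Module()
            d = n_in if layer == 0 else units
            cell.W = _param(rng, (d, 3 * units), fan_in=d, fan_out=units)
            cell.U = _param(rng, (units, 3 * units), fan_in=units, fan_out=units)
            cell.b = _zeros((3 * units,))
            cell.h0 = _zeros((units,)) if learned_init else Tensor(np.zeros(units))
            self.cells.append(cell)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] == 0:
            raise EmptyInputError("cannot encode an empty token sequence")
        batch, n, _ = x.shape
        H = self.units
        seq = x
        for cell in self.cells:
            h = Tensor(np.ones((batch, 1))) @ cell.h0.reshape(1, H)
            outputs = []
            for t in range(n):
                xt = seq[:, t, :]
                xW = xt @ cell.W
                hU = h @ cell.U
                z = (xW[:, :H] + hU[:, :H] + cell.b[:H]).sigmoid()
                r = (xW[:, H:2 * H] + hU[:, H:2 * H] + cell.b[H:2 * H]).sigmoid()
                nn = (xW[:, 2 * H:] + r * hU[:, 2 * H:] + cell.b[2 * H:]).tanh()
                h = (1.0 - z) * nn + z * h
                outputs.append(h)
            seq = stack(outputs, axis=1)
        return h


class BoWEncoder(Module):
    """Mean of token vectors -> tanh hidden layer -> linear output."""

    def __init__(self, rng: np.random.Generator, n_in: int, units: int, n_out: int):
        self.hidden = Linear(rng, n_in, units)
        self.out = Linear(rng, units, n_out)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] == 0:
            raise EmptyInputError("cannot encode an empty token sequence")
        return self.out(self.hidden(x.mean(axis=1)).tanh())


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim)); self.gamma.requires_grad = True
        self.beta = _zeros((dim,))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


def sinusoidal_positions(n: int, dim: int) -> Array:
    """Classic fixed sine/cosine position encodings (n x dim)."""
    pos = np.arange(n)[:, None]
    i = np.arange(dim)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.empty((n, dim))
    enc[:, 0::2] = np.sin(angles[:, 0::2])
    enc[:, 1::2] = np.cos(angles[:, 1::2])
    return enc


class TransformerBlock(Module):
    def __init__(self, rng: np.random.Generator, dim: int, heads: int,
                 ff_mult: int = 4):
        if dim % heads:
            raise ValueError("hidden size must be divisible by the head count")
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.Wq = Linear(rng, dim, dim)
        self.Wk = Linear(rng, dim, dim)
        self.Wv = Linear(rng, dim, dim)
        self.Wo = Linear(rng, dim, dim)
        self.ff1 = Linear(rng, dim, ff_mult * dim)
        self.ff2 = Linear(rng, ff_mult * dim, dim)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)

    def _attend(self, x: Tensor) -> Tensor:
        batch, n, _ = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(batch, n, self.heads, self.dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.Wq(x)), split(self.Wk(x)), split(self.Wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(batch, n, self.dim)
        return self.Wo(ctx)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self._attend(x))
        return self.ln2(x + self.ff2(self.ff1(x).relu()))


class TransformerEncoder(Module):
    """Stacked self-attention encoders over grounded token sequences.

    Token vectors are linearly lifted to the hidden size, summed with
    sinusoidal position encodings, contextualized by ``layers`` blocks,
    mean-pooled over positions and projected to the image space.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, units: int,
                 n_out: int, layers: int = 1, heads: int = 16):
        self.lift = Linear(rng, n_in, units)
        self.blocks = [TransformerBlock(rng, units, heads) for _ in range(layers)]
        self.out = Linear(rng, units, n_out)
        self.units = units

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] == 0:
            raise EmptyInputError("cannot encode an empty token sequence")
        h = self.lift(x) + Tensor(sinusoidal_positions(x.shape[1], self.units))
        for block in self.blocks:
            h = block(h)
        return self.out(h.mean(axis=1))


class BatchNorm1d(Module):
    """Batch normalization with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim)); self.gamma.requires_grad = True
        self.beta = _zeros((dim,))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.train_mode:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            return centered / (var + self.eps).sqrt() * self.gamma + self.beta
        xc = x - Tensor(self.running_mean)
        return (xc / Tensor(np.sqrt(self.running_var + self.eps))
                * self.gamma + self.beta)


class Dropout(Module):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.train_mode or self.rate <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)
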