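"""Minimal dense neural-network layers on numpy with explicit backprop.

The models in this package are small (two transformer layers, 64 wide), so
layers are implemented directly on numpy arrays with hand-derived gradients:
each layer's ``forward`` caches what its ``backward`` needs, ``backward``
accumulates parameter gradients and returns the input gradient.  Every
gradient is verified against central finite differences in the test suite.

Conventions: sequence inputs are (batch, length, d_model); attention is
pre-norm residual as in GPT-2-style encoders; AdamW uses decoupled weight
decay applied only to weight matrices (never to biases, gains or
embeddings) and a linear learning-rate warmup followed by a constant rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class Param:
    value: np.ndarray
    decay: bool = True
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[tuple[str, Param]]:
        out: list[tuple[str, Param]] = []
        for name, attr in vars(self).items():
            if isinstance(attr, Param):
                out.append((name, attr))
            elif isinstance(attr, Module):
                out.extend((f"{name}.{k}", p) for k, p in attr.params())
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend((f"{name}.{i}.{k}", p) for k, p in item.params())
        return out

    def zero_grad(self) -> None:
        flat = getattr(self, "_flat", None)
        if flat is not None:
            flat[1][...] = 0.0
            return
        for _, p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.params())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, p in own.items():
            if p.value.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.value[...] = state[k]


def flatten_module(module: Module) -> None:
    """Re-home every parameter and gradient into one contiguous buffer.

    Afterwards each Param's value/grad are views into the shared buffers, so
    the optimizer and zero_grad run as a handful of vectorized operations
    instead of hundreds of small ones.  Callers must mutate parameters in
    place (``p.value[...] = x``), never rebind them.
    """
    params = module.params()
    total = sum(p.value.size for _, p in params)
    buf = np.empty(total)
    gbuf = np.zeros(total)
    decay = np.zeros(total, dtype=bool)
    i = 0
    for _, p in params:
        n = p.value.size
        buf[i:i + n] = p.value.ravel()
        p.value = buf[i:i + n].reshape(p.value.shape)
        p.grad = gbuf[i:i + n].reshape(p.value.shape)
        decay[i:i + n] = p.decay
        i += n
    module._flat = (buf, gbuf, decay)


def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, d_in, d_out), decay=True)
        self.b = Param(np.zeros(d_out), decay=False)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T


class Embedding(Module):
    def __init__(self, n_tokens: int, d: int, rng: np.random.Generator):
        self.E = Param(rng.normal(0.0, 0.02, size=(n_tokens, d)), decay=False)
        self._tokens: np.ndarray | None = None

    def forward(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens)
        if tokens.min() < 0 or tokens.max() >= self.E.value.shape[0]:
            raise IndexError("token out of vocabulary range")
        self._tokens = tokens
        return self.E.value[tokens]

    def backward(self, dy: np.ndarray) -> None:
        np.add.at(self.E.grad, self._tokens, dy)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Param(np.ones(d), decay=False)
        self.b = Param(np.zeros(d), decay=False)
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.g.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.g.grad += (dy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dxhat = dy * self.g.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Module):
    """Inverted dropout; a no-op when p == 0 or in eval mode."""

    def __init__(self, p: float):
        self.p = p
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, L, _ = x.shape
        return x.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] == 1:
            # one-token sequence: softmax over a single key is 1, so the
            # block reduces to the value/output projections
            self._cache = None
            return self.wo.forward(self.wv.forward(x))
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / math.sqrt(self.dh)
        a = _softmax(scores, axis=-1)
        o = a @ v
        self._cache = (q, k, v, a)
        return self.wo.forward(self._merge(o))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            return self.wv.backward(self.wo.backward(dy))
        q, k, v, a = self._cache
        do = self._split(self.wo.backward(dy))
        da = do @ v.transpose(0, 1, 3, 2)
        dv = a.transpose(0, 1, 3, 2) @ do
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        ds /= math.sqrt(self.dh)
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        dx = self.wq.backward(self._merge(dq))
        dx = dx + self.wk.backward(self._merge(dk))
        dx = dx + self.wv.backward(self._merge(dv))
        return dx


class TransformerLayer(Module):
    """Pre-norm residual block: x + attn(ln(x)), then x + ff(ln(x))."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.relu = ReLU()
        self.ff2 = Linear(d_ff, d_model, rng)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = x + self.drop1.forward(self.attn.forward(self.ln1.forward(x)), train, rng)
        x = x + self.drop2.forward(
            self.ff2.forward(self.relu.forward(self.ff1.forward(self.ln2.forward(x)))),
            train, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.drop2.backward(dy)
        d = self.ln2.backward(self.ff1.backward(self.relu.backward(self.ff2.backward(d))))
        dy = dy + d
        d = self.drop1.backward(dy)
        d = self.ln1.backward(self.attn.backward(d))
        return dy + d


class TransformerEncoder(Module):
    def __init__(self, d_model: int, n_layers: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.layers = [TransformerLayer(d_model, n_heads, d_ff, rng, dropout)
                       for _ in range(n_layers)]
        self.ln_f = LayerNorm(d_model)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return self.ln_f.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.ln_f.backward(dy)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def l2_normalize(x: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unit normalization; returns (y, norms) for the backward pass."""
    norms = np.sqrt((x * x).sum(axis=-1, keepdims=True)) + eps
    return x / norms, norms


def l2_normalize_backward(dy: np.ndarray, y: np.ndarray, norms: np.ndarray) -> np.ndarray:
    return (dy - y * (y * dy).sum(axis=-1, keepdims=True)) / norms


class MLPHead(Module):
    """One hidden ReLU layer with dropout, for classification or regression."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator, dropout: float = 0.2):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.relu = ReLU()
        self.drop = Dropout(dropout)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.drop.forward(self.relu.forward(self.fc1.forward(x)), train, rng)
        return self.fc2.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.relu.backward(self.drop.backward(
            self.fc2.backward(dy))))


class AdamW:
    """Adam with decoupled weight decay and linear warmup to a constant rate.

    Accepts either a (name, Param) sequence or a Module; a module whose
    parameters were flattened with :func:`flatten_module` is stepped through
    the shared buffers in a few vectorized operations.
    """

    def __init__(self, params: "Sequence[tuple[str, Param]] | Module", lr: float,
                 warmup_steps: int = 0, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self._flat = None
        if isinstance(params, Module):
            if getattr(params, "_flat", None) is None:
                flatten_module(params)
            self._flat = params._flat
            self.params = params.params()
        else:
            self.params = list(params)
        self.base_lr = lr
        self.warmup_steps = max(int(warmup_steps), 0)
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        if self._flat is not None:
            n = self._flat[0].size
            self.m = np.zeros(n)
            self.v = np.zeros(n)
        else:
            self.m = {k: np.zeros_like(p.value) for k, p in self.params}
            self.v = {k: np.zeros_like(p.value) for k, p in self.params}

    def current_lr(self) -> float:
        if self.warmup_steps and self.t < self.warmup_steps:
            return self.base_lr * (self.t + 1) / self.warmup_steps
        return self.base_lr

    def step(self) -> float:
        lr = self.current_lr()
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        if self._flat is not None:
            buf, gbuf, decay = self._flat
            self.m *= self.b1
            self.m += (1 - self.b1) * gbuf
            self.v *= self.b2
            self.v += (1 - self.b2) * gbuf * gbuf
            buf -= lr * (self.m / c1) / (np.sqrt(self.v / c2) + self.eps)
            if self.weight_decay:
                buf[decay] -= lr * self.weight_decay * buf[decay]
            return lr
        for k, p in self.params:
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.value -= lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
            if self.weight_decay and p.decay:
                p.value -= lr * self.weight_decay * p.value
        return lr


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x (test utility)."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
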