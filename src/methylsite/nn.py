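"""Minimal dense/attention layers with explicit backward passes, plus Adam.

Everything is float64 NumPy. Each layer caches what its backward pass needs
during forward; ``backward`` returns the gradient with respect to the input
and stores parameter gradients on the layer's :class:`Param` objects.
Gradients are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from scipy.special import erf

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Dense:
    """Affine map on the last axis."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else math.sqrt(1.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, (n_in, n_out)) if scale else
                       np.zeros((n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        gf = g.reshape(-1, g.shape[-1])
        self.W.grad = xf.T @ gf
        self.b.grad = gf.sum(axis=0)
        return g @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def state(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.W": self.W.value, f"{prefix}.b": self.b.value}


class LayerNorm:
    """Normalization over the last axis with learned gain and bias."""

    def __init__(self, width: int, eps: float = 1e-5):
        self.gain = Param(np.ones(width))
        self.bias = Param(np.zeros(width))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = xc * inv
        self._inv = inv
        return self.gain.value * self._xhat + self.bias.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        lead = tuple(range(g.ndim - 1))
        self.gain.grad = (g * xhat).sum(axis=lead)
        self.bias.grad = g.sum(axis=lead)
        dxhat = g * self.gain.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)

    def params(self) -> list[Param]:
        return [self.gain, self.bias]

    def state(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.gain": self.gain.value, f"{prefix}.bias": self.bias.value}


class Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an RNG"
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention with optional key masking."""

    def __init__(self, rng: np.random.Generator, width: int, n_heads: int):
        if width % n_heads != 0:
            raise ValueError(f"n_heads {n_heads} must divide width {width}")
        self.width = width
        self.n_heads = n_heads
        self.dk = width // n_heads
        self.wq = Dense(rng, width, width)
        self.wk = Dense(rng, width, width)
        self.wv = Dense(rng, width, width)
        self.wo = Dense(rng, width, width)

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, x: np.ndarray, key_mask: np.ndarray | None) -> np.ndarray:
        Q = self._split(self.wq.forward(x))
        K = self._split(self.wk.forward(x))
        V = self._split(self.wv.forward(x))
        scores = Q @ K.transpose(0, 1, 3, 2) / math.sqrt(self.dk)
        if key_mask is not None:
            scores = scores + (key_mask[:, None, None, :] - 1.0) * 1e9
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        A = e / e.sum(axis=-1, keepdims=True)
        ctx = A @ V
        self._cache = (Q, K, V, A)
        return self.wo.forward(self._merge(ctx))

    def backward(self, g: np.ndarray) -> np.ndarray:
        Q, K, V, A = self._cache
        g_ctx = self._split(self.wo.backward(g))
        gA = g_ctx @ V.transpose(0, 1, 3, 2)
        gV = A.transpose(0, 1, 3, 2) @ g_ctx
        dS = A * (gA - (gA * A).sum(axis=-1, keepdims=True))
        dS /= math.sqrt(self.dk)
        gQ = dS @ K
        gK = dS.transpose(0, 1, 3, 2) @ Q
        gx = self.wq.backward(self._merge(gQ))
        gx = gx + self.wk.backward(self._merge(gK))
        gx = gx + self.wv.backward(self._merge(gV))
        return gx

    def params(self) -> list[Param]:
        return [p for d in (self.wq, self.wk, self.wv, self.wo) for p in d.params()]

    def state(self, prefix: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, d in (("wq", self.wq), ("wk", self.wk), ("wv", self.wv),
                        ("wo", self.wo)):
            out.update(d.state(f"{prefix}.{name}"))
        return out


class EncoderBlock:
    """Pre-norm transformer encoder block with a GELU feed-forward of width
    4× the model width."""

    def __init__(self, rng: np.random.Generator, width: int, n_heads: int,
                 dropout: float):
        self.ln1 = LayerNorm(width)
        self.attn = MultiHeadSelfAttention(rng, width, n_heads)
        self.drop1 = Dropout(dropout)
        self.ln2 = LayerNorm(width)
        self.ff1 = Dense(rng, width, 4 * width)
        self.ff2 = Dense(rng, 4 * width, width)
        self.drop2 = Dropout(dropout)

    def forward(self, x: np.ndarray, key_mask: np.ndarray | None,
                train: bool, rng: np.random.Generator | None) -> np.ndarray:
        a = x + self.drop1.forward(
            self.attn.forward(self.ln1.forward(x), key_mask), train, rng
        )
        h = self.ff1.forward(self.ln2.forward(a))
        self._h = h
        f = self.ff2.forward(gelu(h))
        return a + self.drop2.forward(f, train, rng)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gf = self.drop2.backward(g)
        gh = self.ff2.backward(gf) * gelu_grad(self._h)
        ga = g + self.ln2.backward(self.ff1.backward(gh))
        gattn = self.attn.backward(self.drop1.backward(ga))
        return ga + self.ln1.backward(gattn)

    def params(self) -> list[Param]:
        return (self.ln1.params() + self.attn.params() + self.ln2.params()
                + self.ff1.params() + self.ff2.params())

    def state(self, prefix: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        out.update(self.ln1.state(f"{prefix}.ln1"))
        out.update(self.attn.state(f"{prefix}.attn"))
        out.update(self.ln2.state(f"{prefix}.ln2"))
        out.update(self.ff1.state(f"{prefix}.ff1"))
        out.update(self.ff2.state(f"{prefix}.ff2"))
        return out


class DenseStack:
    """ReLU dense stack with dropout, ending in a single-logit layer."""

    def __init__(self, rng: np.random.Generator, n_in: int,
                 hidden: Iterable[int], dropout: float):
        widths = list(hidden)
        self.layers: list[Dense] = []
        self.drops: list[Dropout] = []
        prev = n_in
        for w in widths:
            self.layers.append(Dense(rng, prev, w))
            self.drops.append(Dropout(dropout))
            prev = w
        self.out = Dense(rng, prev, 1)

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        self._pre = []
        for layer, drop in zip(self.layers, self.drops):
            z = layer.forward(x)
            self._pre.append(z)
            x = drop.forward(np.maximum(z, 0.0), train, rng)
        return self.out.forward(x)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = self.out.backward(g[..., None])
        for layer, drop, z in zip(
            reversed(self.layers), reversed(self.drops), reversed(self._pre)
        ):
            gx = drop.backward(gx) * (z > 0.0)
            gx = layer.backward(gx)
        return gx

    def params(self) -> list[Param]:
        out = [p for layer in self.layers for p in layer.params()]
        return out + self.out.params()

    def state(self, prefix: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            out.update(layer.state(f"{prefix}.h{i}"))
        out.update(self.out.state(f"{prefix}.out"))
        return out


def load_layer_state(obj, prefix: str, arrays: dict[str, np.ndarray]) -> None:
    """Restore parameter values for any layer exposing ``state``."""
    current = obj.state(prefix)
    params = obj.params()
    # state() and params() enumerate in the same structural order
    for (key, _), p in zip(current.items(), params):
        p.value = np.array(arrays[key], dtype=np.float64)


class Adam:
    """Adam with lazy per-parameter state: only parameters that received a
    gradient in the current step are touched, so heads excluded from a batch
    stay bitwise unchanged."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._state: dict[int, tuple[np.ndarray, np.ndarray, int]] = {}

    def step(self, params: Iterable[Param]) -> None:
        for p in params:
            if p.grad is None:
                continue
            m, v, t = self._state.get(id(p), (np.zeros_like(p.value),
                                              np.zeros_like(p.value), 0))
            t += 1
            m = self.beta1 * m + (1.0 - self.beta1) * p.grad
            v = self.beta2 * v + (1.0 - self.beta2) * p.grad * p.grad
            mhat = m / (1.0 - self.beta1 ** t)
            vhat = v / (1.0 - self.beta2 ** t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            self._state[id(p)] = (m, v, t)

    def zero_grad(self, params: Iterable[Param]) -> None:
        for p in params:
            p.grad = None
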