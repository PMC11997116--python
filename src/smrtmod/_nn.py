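"""Minimal numpy neural-network layers with explicit backward passes.

Supports exactly what the modification scorer needs: same-padded Conv1d,
batch/layer normalization, ReLU/GELU, dropout, multi-head self-attention,
dense layers, softmax cross-entropy, and Adam.  Shapes follow the
``(batch, length, channels)`` convention.  Analytic gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

#: computation dtype; float32 for speed, settable to float64 (e.g. for
#: finite-difference gradient checks) before a network is built
DTYPE = np.float32

_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 gain: float = 2.0):
        std = np.sqrt(gain / d_in)
        self.W = Param(rng.normal(0.0, std, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.W.value.T


class Conv1dSame(Layer):
    """1-D convolution with same padding, via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.c_in = c_in
        std = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, std, size=(kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        B, L, C = x.shape
        pad = self.k // 2
        xp = np.zeros((B, L + 2 * pad, C), dtype=x.dtype)
        xp[:, pad:pad + L] = x
        patches = np.concatenate([xp[:, i:i + L] for i in range(self.k)], axis=-1)
        self._patches = patches
        self._shape = (B, L, C, pad)
        return patches @ self.W.value + self.b.value

    def backward(self, dout):
        B, L, C, pad = self._shape
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += self._patches.reshape(-1, self.k * C).T @ d2
        self.b.grad += d2.sum(axis=0)
        dpatches = dout @ self.W.value.T
        dxp = np.zeros((B, L + 2 * pad, C), dtype=dout.dtype)
        for i in range(self.k):
            dxp[:, i:i + L] += dpatches[:, :, i * C:(i + 1) * C]
        return dxp[:, pad:pad + L]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GELU(Layer):
    """Exact Gaussian-error-linear unit."""

    def forward(self, x, train):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        return x * self._cdf

    def backward(self, dout):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * self._x ** 2)
        return dout * (self._cdf + self._x * pdf)


class BatchNorm(Layer):
    """Normalization per channel over the batch (and length) axes."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._train = train
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        if not self._train:
            return dxhat * self._istd
        n = self._n
        return (self._istd / n) * (
            n * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class LayerNorm(Layer):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(d))
        self.beta = Param(np.zeros(d))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        d = dout.shape[-1]
        axes = tuple(range(dout.ndim - 1))
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        return (self._istd / d) * (
            d * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=-1, keepdims=True)
        )


class Dropout(Layer):
    def __init__(self, p: float):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, train):
        if not train or self.p == 0.0 or self.rng is None:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p)
                      .astype(x.dtype) / (1.0 - self.p))
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention with ``n_heads`` heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.d = d_model
        std = np.sqrt(1.0 / d_model)
        self.Wqkv = Param(rng.normal(0.0, std, size=(d_model, 3 * d_model)))
        self.bqkv = Param(np.zeros(3 * d_model))
        self.Wo = Param(rng.normal(0.0, std, size=(d_model, d_model)))
        self.bo = Param(np.zeros(d_model))

    def params(self):
        return [self.Wqkv, self.bqkv, self.Wo, self.bo]

    def _split(self, x):
        B, L, _ = x.shape
        return x.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def forward(self, x, train):
        self._x = x
        qkv = x @ self.Wqkv.value + self.bqkv.value
        q, k, v = np.split(qkv, 3, axis=-1)
        q, k, v = self._split(q), self._split(k), self._split(v)
        scores = q @ k.transpose(0, 1, 3, 2) / float(np.sqrt(self.dh))
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        A = e / e.sum(axis=-1, keepdims=True)
        ctx = A @ v
        self._cache = (q, k, v, A)
        merged = self._merge(ctx)
        self._merged = merged
        return merged @ self.Wo.value + self.bo.value

    def backward(self, dout):
        q, k, v, A = self._cache
        d2 = dout.reshape(-1, self.d)
        self.Wo.grad += self._merged.reshape(-1, self.d).T @ d2
        self.bo.grad += d2.sum(axis=0)
        dctx = self._split(dout @ self.Wo.value.T)
        dA = dctx @ v.transpose(0, 1, 3, 2)
        dv = A.transpose(0, 1, 3, 2) @ dctx
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= float(np.sqrt(self.dh))
        dq = dS @ k
        dk = dS.transpose(0, 1, 3, 2) @ q
        dqkv = np.concatenate(
            [self._merge(g) for g in (dq, dk, dv)], axis=-1)
        x2 = self._x.reshape(-1, self.d)
        self.Wqkv.grad += x2.T @ dqkv.reshape(-1, 3 * self.d)
        self.bqkv.grad += dqkv.reshape(-1, 3 * self.d).sum(axis=0)
        return dqkv @ self.Wqkv.value.T


class TransformerBlock(Layer):
    """Pre-layer-norm encoder block: x + MHA(LN(x)), then x + FF(LN(x))."""

    def __init__(self, d_model: int, n_heads: int, ff_dim: int,
                 dropout: float, rng: np.random.Generator):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.drop1 = Dropout(dropout)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Dense(d_model, ff_dim, rng, gain=1.0)
        self.gelu = GELU()
        self.ff2 = Dense(ff_dim, d_model, rng, gain=1.0)
        self.drop2 = Dropout(dropout)

    def params(self):
        out = []
        for l in (self.ln1, self.attn, self.ln2, self.ff1, self.ff2):
            out.extend(l.params())
        return out

    def set_dropout_rng(self, rng):
        self.drop1.rng = rng
        self.drop2.rng = rng

    def forward(self, x, train):
        a = x + self.drop1.forward(
            self.attn.forward(self.ln1.forward(x, train), train), train)
        f = self.ff2.forward(
            self.gelu.forward(self.ff1.forward(self.ln2.forward(a, train),
                                               train), train), train)
        return a + self.drop2.forward(f, train)

    def backward(self, dout):
        df = self.drop2.backward(dout)
        da = dout + self.ln2.backward(
            self.ff1.backward(self.gelu.backward(self.ff2.backward(df))))
        dx = da + self.ln1.backward(
            self.attn.backward(self.drop1.backward(da)))
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
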