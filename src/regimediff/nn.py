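"""Layers and optimizer on top of the autodiff engine.

Only what the model family needs: dense layers, dilated/strided 1-D
convolutions (implemented as gather + matmul so gradients compose), layer
normalization, a small Elman recurrence for the FID embedding network, and
Adam.
"""

from __future__ import annotations

import numpy as np

from . import _engine as E
from ._engine import Tensor


def parameter(data):
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Module:
    def params(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_arrays(self):
        return [p.data for p in self.params()]

    def load_arrays(self, arrays):
        ps = self.params()
        if len(ps) != len(arrays):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(ps, arrays):
            p.data = np.array(a, dtype=np.float64)


class Linear(Module):
    def __init__(self, n_in, n_out, rng):
        self.W = parameter(glorot(rng, (n_in, n_out)))
        self.b = parameter(np.zeros(n_out))

    def __call__(self, x):
        return E.add(E.matmul(x, self.W), self.b)


class Conv1d(Module):
    """1-D convolution on (B, C_in, L) inputs via unfold + matmul.

    ``padding`` is symmetric zero padding; output length is
    floor((L + 2p - dilation*(k-1) - 1)/stride) + 1.
    """

    def __init__(self, c_in, c_out, kernel, rng, stride=1, dilation=1, padding=None):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.stride, self.dilation = stride, dilation
        self.padding = padding if padding is not None else dilation * (kernel - 1) // 2
        self.W = parameter(glorot(rng, (c_in * kernel, c_out)))
        self.b = parameter(np.zeros(c_out))

    def __call__(self, x):
        B, C, L = x.shape
        Lp = L + 2 * self.padding
        span = self.dilation * (self.k - 1) + 1
        Lo = (Lp - span) // self.stride + 1
        if self.padding:
            key = (slice(None), slice(None), slice(self.padding, self.padding + L))
            x = E.unslice(x, key, (B, C, Lp))
        taps = []
        for j in range(self.k):
            start = j * self.dilation
            sl = slice(start, start + (Lo - 1) * self.stride + 1, self.stride)
            taps.append(E.getitem(x, (slice(None), slice(None), sl)))  # (B, C, Lo)
        g = E.concat(taps, axis=1)                      # (B, k*C, Lo)
        g = E.reshape(E.transpose(g, (0, 2, 1)), (B * Lo, self.k * C))
        out = E.add(E.matmul(g, self.W), self.b)        # (B*Lo, c_out)
        out = E.reshape(out, (B, Lo, self.c_out))
        return E.transpose(out, (0, 2, 1))              # (B, c_out, Lo)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x):
        mu = E.mean(x, axis=-1, keepdims=True)
        xc = E.add(x, E.mul(mu, -1.0))
        var = E.mean(E.square(xc), axis=-1, keepdims=True)
        xn = E.mul(xc, E.power(E.add(var, self.eps), -0.5))
        return E.add(E.mul(xn, self.gamma), self.beta)


class ElmanRNN(Module):
    """Plain recurrent layer; final hidden state used as sequence embedding."""

    def __init__(self, n_in, n_hidden, rng):
        self.Wx = parameter(glorot(rng, (n_in, n_hidden)) * 0.5)
        self.Wh = parameter(np.linalg.qr(rng.standard_normal((n_hidden, n_hidden)))[0] * 0.9)
        self.b = parameter(np.zeros(n_hidden))
        self.n_hidden = n_hidden

    def __call__(self, x):
        # x: (B, L, C) -> final hidden (B, H)
        B, L, _ = x.shape
        h = Tensor(np.zeros((B, self.n_hidden)))
        for t in range(L):
            xt = E.getitem(x, (slice(None), t, slice(None)))
            h = E.tanh(E.add(E.add(E.matmul(xt, self.Wx), E.matmul(h, self.Wh)), self.b))
        return h


def sinusoidal_embedding(t, dim, max_period=10000.0):
    """Classic transformer-style positional code for the diffusion step index."""
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    ang = float(t) * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)])


class Adam:
    def __init__(self, params, lr=1e-4, betas=(0.5, 0.9), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
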