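"""Minimal reverse-mode autodiff on numpy arrays.

The package's neural components (reverse denoiser, dual-branch critic, FID
encoder, CCA classifier) are small, so they run on this engine instead of a
deep-learning framework.  Every primitive's backward pass is itself built from
engine primitives, which makes higher-order differentiation work: the WGAN-GP
gradient penalty differentiates the critic's input gradient with respect to
the critic parameters, i.e. it needs backward-of-backward.

Conventions: float64 throughout; ``Tensor.backward()`` writes ``.grad``;
``grad_of`` returns input gradients without touching parameter ``.grad``
buffers (used for the gradient penalty).
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents")

    def __init__(self, data, requires_grad=False, _parents=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        # list of (parent_tensor, grad_fn) where grad_fn(g: Tensor) -> Tensor
        self._parents = _parents if (_parents and _GRAD_ENABLED[-1]) else None

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self):
        grads = _run_backward(self, create_graph=False)
        for t, g in grads.items():
            if t.requires_grad:
                t.grad = g.data if t.grad is None else t.grad + g.data

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return getitem(self, key)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*tensors):
    return _GRAD_ENABLED[-1] and any(
        t.requires_grad or t._parents is not None for t in tensors
    )


def _node(data, parents):
    return Tensor(data, _parents=parents)


def _run_backward(root, create_graph):
    """Topologically traverse the graph from ``root``; return {tensor: grad}."""
    topo, seen, stack = [], set(), [(root, False)]
    while stack:
        t, done = stack.pop()
        if done:
            topo.append(t)
            continue
        if id(t) in seen:
            continue
        seen.add(id(t))
        stack.append((t, True))
        if t._parents:
            for p, _ in t._parents:
                if id(p) not in seen:
                    stack.append((p, False))
    grads = {id(root): Tensor(np.ones_like(root.data))}
    by_id = {id(root): root}
    ctx = no_grad() if not create_graph else None
    if ctx:
        ctx.__enter__()
    try:
        for t in reversed(topo):
            g = grads.get(id(t))
            if g is None or not t._parents:
                continue
            for p, grad_fn in t._parents:
                pg = grad_fn(g)
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
                by_id[id(p)] = p
    finally:
        if ctx:
            ctx.__exit__()
    return {by_id[i]: g for i, g in grads.items()}


def grad_of(output, inputs, create_graph=False):
    """Gradients of scalar ``output`` w.r.t. ``inputs`` (no .grad side effects)."""
    grads = _run_backward(output, create_graph=create_graph)
    return [grads.get(t) if grads.get(t) is not None else Tensor(np.zeros_like(t.data))
            for t in inputs]


# -- broadcasting helpers --------------------------------------------------

def _reduce_to(g, shape):
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    while g.data.ndim > len(shape):
        g = sum_(g, axis=0)
    axes = tuple(i for i, (gs, ts) in enumerate(zip(g.data.shape, shape)) if ts == 1 and gs != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return g


# -- arithmetic primitives -------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data
    if not _track(a, b):
        return Tensor(data)
    return _node(data, [(a, lambda g: _reduce_to(g, a.data.shape)),
                        (b, lambda g: _reduce_to(g, b.data.shape))])


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data
    if not _track(a, b):
        return Tensor(data)
    return _node(data, [(a, lambda g: _reduce_to(mul(g, b.detach()) if not _needs_graph(b) else mul(g, b), a.data.shape)),
                        (b, lambda g: _reduce_to(mul(g, a.detach()) if not _needs_graph(a) else mul(g, a), b.data.shape))])


def _needs_graph(t):
    return t.requires_grad or t._parents is not None


def power(a, p):
    a = as_tensor(a)
    p = float(p)
    data = a.data ** p
    if not _track(a):
        return Tensor(data)
    return _node(data, [(a, lambda g: mul(g, mul(power(a, p - 1.0), p)))])


def sqrt(a):
    return power(a, 0.5)


def exp(a):
    a = as_tensor(a)
    data = np.exp(a.data)
    if not _track(a):
        return Tensor(data)
    out = _node(data, None)
    out._parents = [(a, lambda g: mul(g, out))]
    return out


def log(a):
    a = as_tensor(a)
    data = np.log(a.data)
    if not _track(a):
        return Tensor(data)
    return _node(data, [(a, lambda g: mul(g, power(a, -1.0)))])


def tanh(a):
    a = as_tensor(a)
    data = np.tanh(a.data)
    if not _track(a):
        return Tensor(data)
    out = _node(data, None)
    out._parents = [(a, lambda g: mul(g, add(1.0, mul(mul(out, out), -1.0))))]
    return out


def leaky_relu(a, slope=0.2):
    a = as_tensor(a)
    scale = np.where(a.data > 0, 1.0, slope)
    data = a.data * scale
    if not _track(a):
        return Tensor(data)
    sc = Tensor(scale)
    return _node(data, [(a, lambda g: mul(g, sc))])


# -- shape primitives ------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    data = a.data.reshape(shape)
    if not _track(a):
        return Tensor(data)
    orig = a.data.shape
    return _node(data, [(a, lambda g: reshape(g, orig))])


def transpose(a, axes):
    a = as_tensor(a)
    data = np.transpose(a.data, axes)
    if not _track(a):
        return Tensor(data)
    inv = tuple(np.argsort(axes))
    return _node(data, [(a, lambda g: transpose(g, inv))])


def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)
    if not _track(a):
        return Tensor(data)
    shape = a.data.shape

    def bw(g):
        gd = g
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else axis
            kshape = list(shape)
            for ax in axes:
                kshape[ax] = 1
            gd = reshape(gd, tuple(kshape))
        return broadcast_to(gd, shape)

    return _node(data, [(a, bw)])


def mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else (
        np.prod([a.data.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def broadcast_to(a, shape):
    a = as_tensor(a)
    data = np.broadcast_to(a.data, shape).copy()
    if not _track(a):
        return Tensor(data)
    orig = a.data.shape
    return _node(data, [(a, lambda g: _reduce_to(g, orig))])


def getitem(a, key):
    a = as_tensor(a)
    data = a.data[key]
    if not _track(a):
        return Tensor(data)
    shape = a.data.shape
    return _node(data, [(a, lambda g: unslice(g, key, shape))])


def unslice(g, key, shape):
    """Adjoint of basic slicing: place ``g`` into zeros of ``shape``."""
    g = as_tensor(g)
    data = np.zeros(shape)
    data[key] = g.data
    if not _track(g):
        return Tensor(data)
    return _node(data, [(g, lambda gg: getitem(gg, key))])


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    if not _track(*tensors):
        return Tensor(data)
    parents, start = [], 0
    for t in tensors:
        n = t.data.shape[axis]
        key = [slice(None)] * data.ndim
        key[axis] = slice(start, start + n)
        key = tuple(key)
        parents.append((t, (lambda k: lambda g: getitem(g, k))(key)))
        start += n
    return _node(data, parents)


def take(a, idx, axis=0):
    """Integer-array gather along ``axis`` (embedding lookup / conv unfold)."""
    a = as_tensor(a)
    idx = np.asarray(idx)
    data = np.take(a.data, idx, axis=axis)
    if not _track(a):
        return Tensor(data)
    size = a.data.shape[axis]
    return _node(data, [(a, lambda g: index_add(g, idx, axis, size))])


def index_add(g, idx, axis, size):
    """Adjoint of ``take`` for 1-D index arrays: scatter-add slices of ``g``."""
    g = as_tensor(g)
    idx = np.asarray(idx).ravel()
    shape = list(g.data.shape)
    out_shape = shape[:axis] + [size] + shape[axis + 1:]
    data = np.zeros(out_shape)
    tgt = np.moveaxis(data, axis, 0)
    np.add.at(tgt, idx, np.moveaxis(g.data, axis, 0))
    if not _track(g):
        return Tensor(data)
    return _node(data, [(g, lambda gg: take(gg, idx, axis))])


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data
    if not _track(a, b):
        return Tensor(data)
    return _node(data, [
        (a, lambda g: matmul(g, transpose(b if _needs_graph(b) else b.detach(), (1, 0)))),
        (b, lambda g: matmul(transpose(a if _needs_graph(a) else a.detach(), (1, 0)), g)),
    ])


# -- Fourier primitives ----------------------------------------------------
# One-sided real FFT on the last axis with zero-padding to n_fft.  All three
# primitives are linear maps; each backward is expressed via the others, so
# they are valid under higher-order differentiation.

def _halve_weights(M):
    K = M // 2 + 1
    w = np.full(K, 2.0)
    w[0] = 1.0
    if M % 2 == 0:
        w[-1] = 1.0
    return w


def rfft_real(x, n_fft):
    x = as_tensor(x)
    data = np.fft.rfft(x.data, n=n_fft, axis=-1).real
    if not _track(x):
        return Tensor(data)
    n_in = x.data.shape[-1]
    w = _halve_weights(n_fft)

    def bw(g):
        # adjoint: M * irfft(g / w)[..., :n_in]
        scaled = mul(g, Tensor(n_fft / w))
        return getitem(irfft_parts(scaled, mul(scaled, 0.0), n_fft), (..., slice(0, n_in)))

    return _node(data, [(x, bw)])


def rfft_imag(x, n_fft):
    x = as_tensor(x)
    data = np.fft.rfft(x.data, n=n_fft, axis=-1).imag
    if not _track(x):
        return Tensor(data)
    n_in = x.data.shape[-1]
    w = _halve_weights(n_fft)

    def bw(g):
        scaled = mul(g, Tensor(n_fft / w))
        return getitem(irfft_parts(mul(scaled, 0.0), scaled, n_fft), (..., slice(0, n_in)))

    return _node(data, [(x, bw)])


def irfft_parts(re, im, n_fft):
    """Real inverse FFT of the one-sided spectrum ``re + 1j*im`` (length n_fft)."""
    re, im = as_tensor(re), as_tensor(im)
    data = np.fft.irfft(re.data + 1j * im.data, n=n_fft, axis=-1)
    if not _track(re, im):
        return Tensor(data)
    w = Tensor(_halve_weights(n_fft) / n_fft)
    return _node(data, [
        (re, lambda g: mul(rfft_real(g, n_fft), w)),
        (im, lambda g: mul(rfft_imag(g, n_fft), w)),
    ])


# -- fused per-row FIR (state-conditioned frequency filtering) -------------

def _sliding(xp, m):
    return np.lib.stride_tricks.sliding_window_view(xp, m, axis=-1)


def row_fir(x, k):
    """Same-padded FIR along the last axis with one kernel row per batch row.

    x: (B, L), k: (B, m) with m odd.  out[b, f] = sum_j k[b, j] x[b, f+j-p].
    Backward is composable: the adjoints are themselves FIR-type primitives.
    """
    x, k = as_tensor(x), as_tensor(k)
    m = k.data.shape[-1]
    p = m // 2
    xp = np.pad(x.data, [(0, 0)] * (x.data.ndim - 1) + [(p, p)])
    data = np.einsum("...lm,...m->...l", _sliding(xp, m), k.data)
    if not _track(x, k):
        return Tensor(data)
    return _node(data, [
        (x, lambda g: row_fir(g, getitem(k if _needs_graph(k) else k.detach(),
                                         (..., slice(None, None, -1))))),
        (k, lambda g: row_fir_kgrad(x if _needs_graph(x) else x.detach(), g, m)),
    ])


def row_fir_kgrad(x, g, m):
    """Adjoint of ``row_fir`` w.r.t. the kernel: gk[b, j] = sum_f xp[b, f+j] g[b, f]."""
    x, g = as_tensor(x), as_tensor(g)
    p = m // 2
    xp = np.pad(x.data, [(0, 0)] * (x.data.ndim - 1) + [(p, p)])
    data = np.einsum("...lm,...l->...m", _sliding(xp, m), g.data)
    if not _track(x, g):
        return Tensor(data)
    return _node(data, [
        (x, lambda gg: row_fir(g if _needs_graph(g) else g.detach(),
                               getitem(gg, (..., slice(None, None, -1))))),
        (g, lambda gg: row_fir(x if _needs_graph(x) else x.detach(), gg)),
    ])


# -- composed helpers ------------------------------------------------------

def square(a):
    return mul(a, a)


def softmax(a, axis=-1):
    a = as_tensor(a)
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return mul(e, power(sum_(e, axis=axis, keepdims=True), -1.0))


def log1p(a):
    return log(add(a, 1.0))
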