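"""Reverse denoiser conditioned on latent state and diffusion step.

Each reverse step lifts the latent into the frequency domain with a
fixed-size FFT (zero-padded to the analysis size), applies a
state-conditioned 1-D convolution across frequency bins (shared weights on
real and imaginary parts, preserving linearity), inverts the transform,
truncates back to the latent dimension, adds a step embedding, and applies a
state-conditioned affine (FiLM) modulation.  The cleaned latent is decoded
by a dilated temporal convolution stack followed by two per-position linear
projections to the channel dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _engine as E
from . import nn
from ._engine import Tensor
from .diffusion import DiffusionSchedule, sample_state_noise
from .spectral_states import StateModel
from .windowing import aggregate

__all__ = ["ReverseGenerator", "GeneratedSequence", "reverse_step",
           "generate_window", "generate_sequence", "sample_state_path"]


@dataclass
class GeneratedSequence:
    """A synthesized sequence plus the provenance needed to reproduce it."""

    values: np.ndarray               # (covered_length, C)
    label: Optional[int]
    state_path: np.ndarray           # (N,)
    seed: Optional[int] = None
    checkpoint_id: str = ""


class ReverseGenerator(nn.Module):
    """All learnable pieces of the reverse process.

    Parameters: a linear encoder (window -> latent z_0), per-state
    frequency-filter kernels phi(s) (initialized to the identity filter),
    FiLM tables gamma(s)/beta(s), a two-layer perceptron on a sinusoidal
    step code, and the temporal-convolution decoder (3 layers, kernel 5,
    dilations 1-2-4).
    """

    def __init__(self, S: int, l: int = 64, channels: int = 1, d: int = 64,
                 fft_size: int = 256, filter_kernel: int = 5, hidden: int = 16,
                 step_dim: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.S, self.l, self.channels, self.d = S, l, channels, d
        self.fft_size, self.filter_kernel = fft_size, filter_kernel
        self.step_dim = step_dim
        self.encoder = nn.Linear(l * channels, d, rng)
        filt = np.zeros((S, filter_kernel))
        filt[:, filter_kernel // 2] = 1.0                      # identity filter
        self.state_filters = nn.parameter(filt + 0.01 * rng.standard_normal(filt.shape))
        self.film_gamma = nn.parameter(np.ones((S, d)))
        self.film_beta = nn.parameter(np.zeros((S, d)))
        self.step_fc1 = nn.Linear(step_dim, 32, rng)
        self.step_fc2 = nn.Linear(32, d, rng)
        self.dec_conv = [
            nn.Conv1d(1, hidden, 5, rng, dilation=1),
            nn.Conv1d(hidden, hidden, 5, rng, dilation=2),
            nn.Conv1d(hidden, hidden, 5, rng, dilation=4),
        ]
        self.dec_fc1 = nn.Linear(hidden, hidden, rng)
        self.dec_fc2 = nn.Linear(hidden, channels, rng)
        if l != d:
            # fixed linear resampling from d latent positions to l samples
            pos = np.linspace(0, d - 1, l)
            lo = np.floor(pos).astype(int)
            hi = np.minimum(lo + 1, d - 1)
            R = np.zeros((d, l))
            R[lo, np.arange(l)] += 1 - (pos - lo)
            R[hi, np.arange(l)] += pos - lo
            self._resample = Tensor(R)
        else:
            self._resample = None

    # -- pieces ------------------------------------------------------------
    def encode(self, windows: np.ndarray) -> Tensor:
        """z_0 = Enc(x^(n)): learned linear projection of the flat window."""
        w = np.asarray(windows, dtype=np.float64).reshape(len(windows), -1)
        return self.encoder(Tensor(w))

    def step_embedding(self, t: int) -> Tensor:
        code = Tensor(nn.sinusoidal_embedding(t, self.step_dim)[None, :])
        return self.step_fc2(E.tanh(self.step_fc1(code)))      # (1, d)

    def _step_embeddings_upto(self, T: int) -> Tensor:
        codes = Tensor(np.stack([nn.sinusoidal_embedding(t, self.step_dim)
                                 for t in range(T)]))
        return self.step_fc2(E.tanh(self.step_fc1(codes)))     # (T, d)

    def _gather_state_params(self, states):
        states = np.asarray(states, dtype=int)
        if np.any(states < 0) or np.any(states >= self.S):
            raise ValueError("unknown state id")
        kern = E.take(self.state_filters, states, axis=0)      # (B, k)
        kern2 = E.concat([kern, kern], axis=0)                 # shared re/im weights
        gamma = E.take(self.film_gamma, states, axis=0)
        beta = E.take(self.film_beta, states, axis=0)
        return kern2, gamma, beta

    def _reverse_step_gathered(self, z, kern2, gamma, beta, step_emb) -> Tensor:
        B = z.shape[0]
        zr = E.rfft_real(z, self.fft_size)                     # (B, K)
        zi = E.rfft_imag(z, self.fft_size)
        filt = E.row_fir(E.concat([zr, zi], axis=0), kern2)    # (2B, K)
        fr = E.getitem(filt, (slice(0, B), slice(None)))
        fi = E.getitem(filt, (slice(B, 2 * B), slice(None)))
        zt = E.getitem(E.irfft_parts(fr, fi, self.fft_size),
                       (slice(None), slice(0, self.d)))
        zt = E.add(zt, step_emb)
        return E.add(E.mul(gamma, zt), beta)

    def reverse_step(self, z_next, states, t: int) -> Tensor:
        """One denoising step (deterministic given parameters)."""
        if not (0 <= t < 10 ** 9):
            raise ValueError("negative step index")
        z = z_next if isinstance(z_next, Tensor) else Tensor(z_next)
        return self._reverse_step_gathered(z, *self._gather_state_params(states),
                                           self.step_embedding(t))

    def reverse_chain(self, z_T, states, schedule: DiffusionSchedule,
                      fused: bool = True) -> Tensor:
        """T denoising steps with the window's state held fixed.

        The default path runs a hand-fused forward/backward over all steps
        (first-order gradients only); ``fused=False`` builds the per-step
        graph instead, which supports arbitrary differentiation and is used
        to cross-check the fused implementation.
        """
        if schedule.T == 0:
            return z_T if isinstance(z_T, Tensor) else Tensor(z_T)
        if fused and not isinstance(z_T, Tensor):
            states = np.asarray(states, dtype=int)
            if np.any(states < 0) or np.any(states >= self.S):
                raise ValueError("unknown state id")
            kern = E.take(self.state_filters, states, axis=0)
            gamma = E.take(self.film_gamma, states, axis=0)
            beta = E.take(self.film_beta, states, axis=0)
            embs = self._step_embeddings_upto(schedule.T)
            return _fused_reverse_chain(np.asarray(z_T, dtype=np.float64),
                                        kern, gamma, beta, embs,
                                        self.fft_size, self.d)
        z = z_T if isinstance(z_T, Tensor) else Tensor(z_T)
        kern2, gamma, beta = self._gather_state_params(states)
        embs = self._step_embeddings_upto(schedule.T)
        for t in range(schedule.T - 1, -1, -1):
            emb = E.getitem(embs, (slice(t, t + 1), slice(None)))
            z = self._reverse_step_gathered(z, kern2, gamma, beta, emb)
        return z

    def decode(self, z0: Tensor) -> Tensor:
        """Dec_theta: latent (B, d) -> segment (B, l, C)."""
        B = z0.shape[0]
        h = E.reshape(z0, (B, 1, self.d))
        for conv in self.dec_conv:
            h = E.leaky_relu(conv(h), 0.2)
        h = E.transpose(h, (0, 2, 1))                          # (B, d, hidden)
        if self._resample is not None:
            h = E.transpose(h, (0, 2, 1))
            hidden = h.shape[1]
            h = E.reshape(h, (B * hidden, self.d))
            h = E.matmul(h, self._resample)
            h = E.reshape(h, (B, hidden, self.l))
            h = E.transpose(h, (0, 2, 1))                      # (B, l, hidden)
        hidden = h.shape[-1]
        flat = E.reshape(h, (B * h.shape[1], hidden))
        out = self.dec_fc2(E.leaky_relu(self.dec_fc1(flat), 0.2))
        return E.reshape(out, (B, self.l, self.channels))

    # -- checkpointing -----------------------------------------------------
    def save(self, path, extra_meta=None):
        meta = {"S": self.S, "l": self.l, "channels": self.channels,
                "d": self.d, "fft_size": self.fft_size,
                "filter_kernel": self.filter_kernel,
                "extra": extra_meta or {}}
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            gen = cls(S=meta["S"], l=meta["l"], channels=meta["channels"],
                      d=meta["d"], fft_size=meta["fft_size"],
                      filter_kernel=meta["filter_kernel"])
            gen.load_arrays([z[f"p{i}"] for i in range(len(gen.params()))])
        return gen


def _fused_reverse_chain(z_T: np.ndarray, kern, gamma, beta, embs,
                         fft_size: int, d: int):
    """All T reverse steps as one graph node (hand-written BPTT backward).

    Numerically identical to composing ``_reverse_step_gathered``; provides
    first-order gradients w.r.t. the state filters, FiLM tables and step
    embeddings.  z_T is treated as a constant (it is sampled noise).
    """
    M, K = fft_size, fft_size // 2 + 1
    m = kern.shape[1]
    p = m // 2
    w = np.full(K, 2.0)
    w[0] = 1.0
    if M % 2 == 0:
        w[-1] = 1.0
    k_np, g_np, b_np, e_np = kern.data, gamma.data, beta.data, embs.data
    T = e_np.shape[0]
    slide = np.lib.stride_tricks.sliding_window_view

    z = z_T
    Z_cache, u_cache = [], []
    for s in range(T):
        t = T - 1 - s
        Z = np.fft.rfft(z, n=M, axis=-1)
        Zp = np.pad(Z, [(0, 0), (p, p)])
        F = np.einsum("bfj,bj->bf", slide(Zp, m, axis=-1), k_np)
        u = np.fft.irfft(F, n=M, axis=-1)[:, :d] + e_np[t]
        z = g_np * u + b_np
        Z_cache.append(Z)
        u_cache.append(u)
    out_data = z

    cache = {}

    def _backward(g):
        key = id(g)
        if key not in cache:
            gz = g.data
            dk = np.zeros_like(k_np)
            dg = np.zeros_like(g_np)
            db = np.zeros_like(b_np)
            de = np.zeros_like(e_np)
            kflip = k_np[:, ::-1]
            for s in range(T - 1, -1, -1):
                t = T - 1 - s
                u = u_cache[s]
                dg += gz * u
                db += gz
                du = gz * g_np
                de[t] += du.sum(axis=0)
                dF = (w / M) * np.fft.rfft(du, n=M, axis=-1)
                dFp = np.pad(dF, [(0, 0), (p, p)])
                dZ = np.einsum("bfj,bj->bf", slide(dFp, m, axis=-1), kflip)
                Zp = np.pad(Z_cache[s], [(0, 0), (p, p)])
                dk += np.einsum("bfj,bf->bj", slide(Zp, m, axis=-1),
                                np.conj(dF)).real
                gz = M * np.fft.irfft(dZ / w, n=M, axis=-1)[:, :d]
            cache[key] = (dk, dg, db, de)
        return cache[key]

    return E._node(out_data, [
        (kern, lambda g: Tensor(_backward(g)[0])),
        (gamma, lambda g: Tensor(_backward(g)[1])),
        (beta, lambda g: Tensor(_backward(g)[2])),
        (embs, lambda g: Tensor(_backward(g)[3])),
    ])


# -- functional wrappers mirroring the module surface ----------------------

def reverse_step(z_next, state, t, params: ReverseGenerator):
    states = np.full(np.atleast_2d(z_next).shape[0], int(state))
    return params.reverse_step(np.atleast_2d(z_next), states, t)


def generate_window(state: int, schedule: DiffusionSchedule, params: ReverseGenerator,
                    mask_bank: np.ndarray, rng: np.random.Generator,
                    size: int = 1) -> np.ndarray:
    """Sample z_T with the state's mask-shaped noise, denoise, decode."""
    with E.no_grad():
        z_T = sample_state_noise(np.asarray(mask_bank)[state], params.d,
                                 params.fft_size, rng, size=size)
        z_T = np.atleast_2d(z_T)
        z0 = params.reverse_chain(z_T, np.full(size, state), schedule)
        seg = params.decode(z0).data
    return seg[0] if size == 1 else seg


def sample_state_path(state_model: StateModel, label: Optional[int], n_windows: int,
                      rng: np.random.Generator, no_markov: bool = False) -> np.ndarray:
    """First state from the class's empirical occupancy, then the Markov prior."""
    S = state_model.S
    if label is not None and state_model.cluster_to_class is not None:
        class_states = state_model.states_for_class(label)
    else:
        class_states = np.arange(S)
    if no_markov:
        return rng.choice(S, size=n_windows)
    if state_model.class_state_occupancy is not None and label is not None:
        occ = state_model.class_state_occupancy[label][class_states]
        p0 = occ / occ.sum() if occ.sum() > 0 else np.full(len(class_states), 1 / len(class_states))
    else:
        p0 = np.full(len(class_states), 1.0 / len(class_states))
    path = np.empty(n_windows, dtype=int)
    path[0] = rng.choice(class_states, p=p0)
    for i in range(1, n_windows):
        path[i] = rng.choice(S, p=state_model.transition[path[i - 1]])
    return path


def generate_sequence(class_label: Optional[int], n_windows: int,
                      state_model: StateModel, params: ReverseGenerator,
                      schedule: DiffusionSchedule, hop: int,
                      rng: np.random.Generator, denorm: Optional[tuple] = None,
                      no_markov: bool = False, no_mask: bool = False,
                      seed: Optional[int] = None) -> GeneratedSequence:
    """Sample a state path, generate every window, overlap-add aggregate.

    ``denorm`` is an optional (mean, std) pair (per channel) used to map
    segments from the normalized training scale back to the source scale.
    """
    path = sample_state_path(state_model, class_label, n_windows, rng, no_markov)
    masks = np.ones_like(state_model.masks) if no_mask else state_model.masks
    with E.no_grad():
        z_T = np.stack([sample_state_noise(masks[s], params.d, params.fft_size, rng)
                        for s in path])
        z0 = params.reverse_chain(z_T, path, schedule)
        segs = params.decode(z0).data                          # (N, l, C)
    if denorm is not None:
        mu, sd = denorm
        segs = segs * np.asarray(sd) + np.asarray(mu)
    values = aggregate(segs, np.arange(n_windows) * hop, params.l)
    return GeneratedSequence(values=values, label=class_label, state_path=path,
                             seed=seed)
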