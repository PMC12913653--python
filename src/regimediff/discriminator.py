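"""Dual-branch critic: temporal realism and global spectral structure.

The time branch is a strided 1-D convolution stack with LeakyReLU and layer
normalization, globally average-pooled.  The spectral branch cuts each
full-length input into non-overlapping 256-sample windows (zero-padding
short sequences to a single window), takes the magnitude of a 256-point FFT
per window, averages the spectra across windows -- making the branch
invariant to window order -- and applies log(1+m).  Both feature vectors
are concatenated and linearly projected to a scalar score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine as E
from . import nn
from ._engine import Tensor

__all__ = ["Critic", "CriticOutput", "spectral_branch_features"]

SPEC_WINDOW = 256
K_BINS = SPEC_WINDOW // 2 + 1


@dataclass
class CriticOutput:
    score: np.ndarray              # (B,)
    time_features: np.ndarray      # (B, F_t)
    spectral_features: np.ndarray  # (B, K*C)


def _spectral_stack(x: Tensor) -> Tensor:
    """Averaged log-magnitude 256-point spectra of non-overlapping windows.

    ``x``: (B, L, C) tensor; returns (B, K*C).  Differentiable.
    """
    B, L, C = x.shape
    n_win = max(1, int(np.ceil(L / SPEC_WINDOW)))
    Lp = n_win * SPEC_WINDOW
    if Lp != L:
        x = E.unslice(x, (slice(None), slice(0, L), slice(None)), (B, Lp, C))
    acc = None
    for wdx in range(n_win):
        seg = E.getitem(x, (slice(None), slice(wdx * SPEC_WINDOW, (wdx + 1) * SPEC_WINDOW),
                            slice(None)))
        seg = E.transpose(seg, (0, 2, 1))                   # (B, C, 256)
        r = E.rfft_real(seg, SPEC_WINDOW)
        i = E.rfft_imag(seg, SPEC_WINDOW)
        # sqrt(.+eps)-sqrt(eps): smooth gradient at zero, exact zero at zero
        mag = E.add(E.sqrt(E.add(E.add(E.square(r), E.square(i)), 1e-24)), -1e-12)
        acc = mag if acc is None else E.add(acc, mag)
    mean_mag = E.mul(acc, 1.0 / n_win)                      # (B, C, K)
    feats = E.log1p(mean_mag)
    return E.reshape(feats, (B, C * K_BINS))


def spectral_branch_features(x: np.ndarray) -> np.ndarray:
    """Parameter-free spectral branch on raw arrays (B, L, C) or (L, C)."""
    arr = np.asarray(x, dtype=np.float64)
    single = arr.ndim <= 2
    if arr.ndim == 1:
        arr = arr[None, :, None]
    elif arr.ndim == 2:
        arr = arr[None, :, :]
    with E.no_grad():
        out = _spectral_stack(Tensor(arr)).data
    return out[0] if single else out


class Critic(nn.Module):
    """Scalar-score dual-branch critic over full reconstructed sequences."""

    def __init__(self, channels: int = 1, time_channels=(32, 64, 64),
                 spec_hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.channels = channels
        c_prev = channels
        self.convs = []
        self.norms = []
        for c in time_channels:
            self.convs.append(nn.Conv1d(c_prev, c, 5, rng, stride=2, padding=2))
            self.norms.append(nn.LayerNorm(c))
            c_prev = c
        self.spec_fc = nn.Linear(K_BINS * channels, spec_hidden, rng)
        self.spec_norm = nn.LayerNorm(spec_hidden)
        self.head = nn.Linear(time_channels[-1] + spec_hidden, 1, rng)

    def time_branch(self, x: Tensor) -> Tensor:
        h = E.transpose(x, (0, 2, 1))                        # (B, C, L)
        for conv, norm in zip(self.convs, self.norms):
            h = E.leaky_relu(conv(h), 0.2)
            h = E.transpose(norm(E.transpose(h, (0, 2, 1))), (0, 2, 1))
        return E.mean(h, axis=2)                             # (B, C_last)

    def forward(self, x) -> tuple:
        """Returns (score (B,1) tensor, time feats, spectral feats)."""
        xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if xt.ndim == 2:
            xt = E.reshape(xt, (*xt.shape, 1))
        tf = self.time_branch(xt)
        sfeat = _spectral_stack(xt)
        sf = self.spec_norm(E.leaky_relu(self.spec_fc(sfeat), 0.2))
        score = self.head(E.concat([tf, sf], axis=1))
        return score, tf, sf

    def __call__(self, x):
        return self.forward(x)[0]

    def score(self, x) -> CriticOutput:
        """Deterministic scalar score plus branch features, on raw arrays."""
        with E.no_grad():
            s, tf, sf = self.forward(x)
        return CriticOutput(score=s.data[:, 0], time_features=tf.data,
                            spectral_features=sf.data)
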