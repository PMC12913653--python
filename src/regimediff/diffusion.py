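"""Forward diffusion with state-conditioned, frequency-shaped Gaussian noise.

The forward chain is the usual variance-preserving update
z_{t+1} = sqrt(alpha_t) z_t + sqrt(1 - alpha_t) eps, but eps is drawn with a
power spectrum proportional to the current latent state's [0,1] frequency
mask instead of being white.  The mask parameterizes a diagonal covariance
over frequency bins; an all-ones mask recovers the standard isotropic chain
exactly.

A K-bin mask has to act on a d-dimensional latent.  The bridge: draw white
time-domain noise of length fft_size, scale its one-sided spectrum by
sqrt(mask), invert, and truncate to d samples.  With mask == 1 this returns
the white noise unchanged, so the unit-variance calibration is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionSchedule", "make_schedule", "sample_state_noise",
           "forward_step", "diffuse"]


@dataclass(frozen=True)
class DiffusionSchedule:
    """Linear variance schedule: beta_t in [beta_min, beta_max], alpha=1-beta."""

    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    @property
    def T(self):
        return len(self.beta)


def make_schedule(T: int, beta_min: float = 1e-4, beta_max: float = 1e-1) -> DiffusionSchedule:
    if T < 0:
        raise ValueError("T must be >= 0")
    if T == 0:
        empty = np.empty(0)
        return DiffusionSchedule(beta=empty, alpha=empty, alpha_bar=empty)
    if not (0.0 < beta_min <= beta_max < 1.0):
        raise ValueError(f"need 0 < beta_min <= beta_max < 1, got [{beta_min}, {beta_max}]")
    beta = np.linspace(beta_min, beta_max, T)
    alpha = 1.0 - beta
    return DiffusionSchedule(beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))


def sample_state_noise(mask: np.ndarray, d: int, fft_size: int,
                       rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Zero-mean noise whose expected power spectrum follows ``mask``.

    Returns (size, d) (or (d,) when size == 1).  mask length must be
    fft_size//2 + 1; entries must be >= 0.  Per-sample variance equals 1
    for an all-ones mask and the all-zeros mask gives the zero vector.
    """
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape != (fft_size // 2 + 1,):
        raise ValueError(f"mask length {mask.shape} != fft_size//2+1 = {fft_size // 2 + 1}")
    if np.any(mask < 0):
        raise ValueError("mask entries must be non-negative")
    white = rng.standard_normal((size, fft_size))
    spec = np.fft.rfft(white, axis=-1) * np.sqrt(mask)
    shaped = np.fft.irfft(spec, n=fft_size, axis=-1)[:, :d]
    return shaped[0] if size == 1 else shaped


def forward_step(z_t: np.ndarray, eps: np.ndarray, alpha_t: float) -> np.ndarray:
    """One forward update: sqrt(alpha_t) z_t + sqrt(1 - alpha_t) eps."""
    if not (0.0 <= alpha_t <= 1.0):
        raise ValueError(f"alpha_t must be in [0, 1], got {alpha_t}")
    return np.sqrt(alpha_t) * z_t + np.sqrt(1.0 - alpha_t) * eps


def diffuse(z0: np.ndarray, state: int, mask_bank: np.ndarray,
            schedule: DiffusionSchedule, rng: np.random.Generator,
            fft_size: int = 256, return_trajectory: bool = True):
    """Run the forward chain for one window; the state is held fixed.

    ``z0`` may be (d,) or (B, d).  Returns the list [z_0 .. z_T] (or just
    z_T when ``return_trajectory`` is False).  Fresh mask-shaped noise is
    drawn at every step; reproducible given the generator state.
    """
    mask_bank = np.asarray(mask_bank)
    if not (0 <= state < mask_bank.shape[0]):
        raise ValueError(f"no mask for state {state}")
    mask = mask_bank[state]
    z = np.atleast_2d(np.asarray(z0, dtype=np.float64))
    d = z.shape[1]
    traj = [z0.copy()]
    for t in range(schedule.T):
        eps = sample_state_noise(mask, d, fft_size, rng, size=z.shape[0])
        eps = np.atleast_2d(eps)
        z = forward_step(z, eps, schedule.alpha[t])
        if return_trajectory:
            traj.append(z[0].copy() if np.asarray(z0).ndim == 1 else z.copy())
    if return_trajectory:
        return traj
    return z[0] if np.asarray(z0).ndim == 1 else z
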