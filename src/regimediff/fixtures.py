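"""Synthetic regime-switching signals with known ground truth.

Every stage of the pipeline is testable without external downloads: the
generator emits class-labeled sequences built from contiguous regime
segments.  The active regime follows a known first-order Markov chain (one
chain per class over that class's regimes); within a regime the signal is a
sum of sinusoids drawn from the regime's frequency band with uniform random
phases, plus additive white Gaussian noise.  Classes differ by their band
sets.  Regime dwell time is a whole number of segments of fixed length
(default: one analysis window), so windows aligned to segment boundaries
are regime-pure and clustering ground truth is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .windowing import TimeSeries

__all__ = ["SyntheticSpec", "make_dataset", "make_ucr_like",
           "two_regime_spec", "window_regimes"]


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic class-structured dataset.

    ``class_bands[c]`` lists the frequency bands (lo, hi) in cycles/sample
    of class c's regimes; ``transitions[c]`` is the row-stochastic regime
    chain of class c.  Regime ids are global: class c's regime r has id
    ``sum(len(class_bands[k]) for k < c) + r``.
    """

    n_classes: int
    class_bands: List[List[Tuple[float, float]]]
    transitions: List[np.ndarray]
    length: int = 96
    channels: int = 1
    samples_per_class: int = 100
    noise_sd: float = 0.3
    dwell: int = 64
    n_sinusoids: int = 1
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.class_bands) != self.n_classes or len(self.transitions) != self.n_classes:
            raise ValueError("class_bands and transitions must have n_classes entries")
        flat = []
        for bands in self.class_bands:
            for lo, hi in bands:
                if not (0.0 < lo <= hi <= 0.5):
                    raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist]")
                flat.append((lo, hi))
        for c, P in enumerate(self.transitions):
            P = np.asarray(P, dtype=np.float64)
            if P.shape != (len(self.class_bands[c]),) * 2 or \
                    not np.allclose(P.sum(axis=1), 1.0) or np.any(P < 0):
                raise ValueError(f"transition matrix for class {c} is not row-stochastic")
            self.transitions[c] = P
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for i in range(len(flat)):
            for j in range(i + 1, len(flat)):
                if flat[i][0] <= flat[j][1] and flat[j][0] <= flat[i][1] and \
                        flat[i] != flat[j]:
                    warnings.warn(f"bands {flat[i]} and {flat[j]} overlap; "
                                  "regimes may not be separable")

    @property
    def n_regimes(self):
        return sum(len(b) for b in self.class_bands)

    def regime_offset(self, label: int) -> int:
        return sum(len(b) for b in self.class_bands[:label])


def _regime_segment(rng, band, n, t0, n_sinusoids, amplitude):
    lo, hi = band
    t = np.arange(t0, t0 + n)
    sig = np.zeros(n)
    for _ in range(n_sinusoids):
        f = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        sig += amplitude * np.sin(2 * np.pi * f * t + phase)
    return sig


def make_dataset(spec: SyntheticSpec):
    """Generate the dataset; returns (series list, per-sequence regime paths).

    Regime paths are per-segment global regime ids (one entry per dwell
    segment); deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_segments = int(np.ceil(spec.length / spec.dwell))
    series, regime_paths = [], []
    for label in range(spec.n_classes):
        bands = spec.class_bands[label]
        P = spec.transitions[label]
        off = spec.regime_offset(label)
        for i in range(spec.samples_per_class):
            path = np.empty(n_segments, dtype=int)
            path[0] = rng.integers(len(bands))
            for s in range(1, n_segments):
                path[s] = rng.choice(len(bands), p=P[path[s - 1]])
            sig = np.concatenate([
                _regime_segment(rng, bands[path[s]], spec.dwell, s * spec.dwell,
                                spec.n_sinusoids, spec.amplitude)
                for s in range(n_segments)])[:spec.length]
            values = np.tile(sig[:, None], (1, spec.channels))
            if spec.noise_sd > 0:
                values = values + rng.normal(0, spec.noise_sd, values.shape)
            series.append(TimeSeries(values=values, label=label,
                                     id=f"syn-c{label}-{i}"))
            regime_paths.append(off + path)
    return series, regime_paths


def window_regimes(regime_path: np.ndarray, dwell: int, l: int, h: int,
                   length: int):
    """Ground-truth regime per analysis window (by window center).

    Returns (regimes, pure) where ``pure[n]`` is True when window n lies
    entirely inside one dwell segment.
    """
    n_windows = (length - l) // h + 1
    regimes = np.empty(n_windows, dtype=int)
    pure = np.empty(n_windows, dtype=bool)
    for n in range(n_windows):
        start, end = n * h, n * h + l - 1
        regimes[n] = regime_path[min((start + end) // 2 // dwell, len(regime_path) - 1)]
        pure[n] = (start // dwell) == (end // dwell)
    return regimes, pure


def two_regime_spec(length: int = 6464, samples: int = 100, noise_sd: float = 0.3,
                    dwell: int = 64, seed: int = 0,
                    p_stay=(0.9, 0.8)) -> SyntheticSpec:
    """Single-class, two-regime chain with disjoint bands (recovery tests)."""
    P = np.array([[p_stay[0], 1 - p_stay[0]], [1 - p_stay[1], p_stay[1]]])
    return SyntheticSpec(
        n_classes=1,
        class_bands=[[(0.05, 0.08), (0.16, 0.20)]],
        transitions=[P],
        length=length, samples_per_class=samples, noise_sd=noise_sd,
        dwell=dwell, seed=seed)


_UCR_LIKE = {
    "ecg200-like": dict(n_classes=2, length=96, instances=200,
                        bands=[[(0.03, 0.06)], [(0.12, 0.18)]]),
    "gunpoint-like": dict(n_classes=2, length=150, instances=200,
                          bands=[[(0.02, 0.05)], [(0.09, 0.14)]]),
}


def make_ucr_like(name: str, seed: int = 0, noise_sd: float = 0.3):
    """Archive-shaped fixture with an official-style disjoint train/test split.

    ``ecg200-like``: 2 classes, length 96, 200 instances; ``gunpoint-like``:
    2 classes, length 150, 200 instances.  Returns (train, test) lists of
    TimeSeries, each split stratified half/half.
    """
    if name not in _UCR_LIKE:
        raise ValueError(f"unknown fixture {name!r}; options: {sorted(_UCR_LIKE)}")
    cfg = _UCR_LIKE[name]
    per_class = cfg["instances"] // cfg["n_classes"]
    spec = SyntheticSpec(
        n_classes=cfg["n_classes"],
        class_bands=cfg["bands"],
        transitions=[np.ones((1, 1)) for _ in range(cfg["n_classes"])],
        length=cfg["length"], samples_per_class=per_class, noise_sd=noise_sd,
        dwell=cfg["length"], seed=seed)
    series, _ = make_dataset(spec)
    rng = np.random.default_rng(seed + 1)
    train, test = [], []
    for label in range(cfg["n_classes"]):
        members = [s for s in series if s.label == label]
        order = rng.permutation(len(members))
        half = len(members) // 2
        train.extend(members[i] for i in order[:half])
        test.extend(members[i] for i in order[half:])
    return train, test
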