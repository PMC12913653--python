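"""Sliding-window segmentation and overlap-add reconstruction.

A length-L sequence is cut into N = floor((L - l)/h) + 1 overlapping windows
of length l at hop h; trailing samples beyond the last full window are
excluded from training and from the reconstructable range.  Reconstruction
averages every window covering a position, which is exact for unmodified
windows and smooths seams for generated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["TimeSeries", "WindowSet", "segment", "aggregate", "coverage_counts"]


@dataclass
class TimeSeries:
    """A labeled, finite real-valued sequence, shape (L, C)."""

    values: np.ndarray
    label: Optional[int] = None
    id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("values must be a (L >= 1, C >= 1) array")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in series {self.id!r}")
        self.values = v

    @property
    def length(self):
        return self.values.shape[0]

    @property
    def channels(self):
        return self.values.shape[1]


@dataclass
class WindowSet:
    """Overlapping l x C segments of one sequence, with their offsets.

    When ``segment`` is called with ``normalize=True`` each window is
    z-normalized and the per-window statistics are retained in
    ``norm_mean`` / ``norm_std`` so generated segments can be put back on
    the source scale.
    """

    windows: np.ndarray           # (N, l, C)
    offsets: np.ndarray           # (N,), 0-based start positions
    window_length: int
    hop: int
    source_length: int
    source_label: Optional[int] = None
    source_id: str = ""
    norm_mean: Optional[np.ndarray] = None   # (N, C)
    norm_std: Optional[np.ndarray] = None    # (N, C)

    @property
    def n_windows(self):
        return self.windows.shape[0]

    @property
    def covered_length(self):
        """Extent reconstructable by overlap-add: end of the last window."""
        return int(self.offsets[-1]) + self.window_length


def segment(ts: TimeSeries, l: int, h: int, normalize: bool = False) -> WindowSet:
    """Cut ``ts`` into N = floor((L-l)/h)+1 overlapping windows.

    Raises ``ValueError`` when l exceeds the sequence length or h < 1.
    """
    L = ts.length
    if l > L:
        raise ValueError(f"window length l={l} exceeds sequence length L={L}")
    if l < 1 or h < 1 or h > l:
        raise ValueError(f"require 1 <= h <= l, got l={l}, h={h}")
    n = (L - l) // h + 1
    offsets = np.arange(n) * h
    windows = np.stack([ts.values[o:o + l] for o in offsets])
    norm_mean = norm_std = None
    if normalize:
        norm_mean = windows.mean(axis=1)                       # (N, C)
        norm_std = windows.std(axis=1)
        norm_std = np.where(norm_std < 1e-12, 1.0, norm_std)   # constant windows
        windows = (windows - norm_mean[:, None, :]) / norm_std[:, None, :]
    return WindowSet(windows=windows, offsets=offsets, window_length=l, hop=h,
                     source_length=L, source_label=ts.label, source_id=ts.id,
                     norm_mean=norm_mean, norm_std=norm_std)


def coverage_counts(offsets, window_length, length):
    """|N_pos|: number of windows covering each position in [0, length)."""
    counts = np.zeros(length)
    for o in np.asarray(offsets, dtype=int):
        counts[o:o + window_length] += 1
    return counts


def aggregate(windows, offsets, window_length: Optional[int] = None) -> np.ndarray:
    """Overlap-add average of ``windows`` (N, l, C) placed at ``offsets``.

    Every covered position is the arithmetic mean over all windows covering
    it; the returned array spans exactly the covered extent.
    """
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim == 2:
        windows = windows[:, :, None]
    if windows.shape[0] == 0:
        raise ValueError("cannot aggregate an empty window collection")
    offsets = np.asarray(offsets, dtype=int)
    l = window_length or windows.shape[1]
    length = int(offsets.max()) + l
    # Mean computed as ref + mean(deviation from ref), where ref is the first
    # window covering each position: bit-exact when overlapping windows agree
    # (the unmodified round trip), ordinary arithmetic mean otherwise.
    ref = np.zeros((length, windows.shape[2]))
    counts = np.zeros(length)
    for w, o in zip(windows[::-1], offsets[::-1]):
        ref[o:o + l] = w
        counts[o:o + l] += 1
    if np.any(counts == 0):
        raise ValueError("offsets leave gaps inside the covered extent")
    acc = np.zeros_like(ref)
    for w, o in zip(windows, offsets):
        acc[o:o + l] += w - ref[o:o + l]
    return ref + acc / counts[:, None]


def aggregate_windowset(ws: WindowSet) -> np.ndarray:
    return aggregate(ws.windows, ws.offsets, ws.window_length)
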