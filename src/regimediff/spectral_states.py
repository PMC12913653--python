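"""Latent spectral regimes: STFT features, k-means states, Markov transitions.

Each window gets one log-magnitude spectral signature (short frames inside
the window are tapered, zero-padded to the analysis FFT size and their
magnitude spectra averaged).  Signatures are clustered into S latent states;
when labels are available each cluster is mapped to its majority class.
Adjacent-window state pairs, counted within each source sequence only, give
the empirical first-order transition matrix.  Per state, the min-max
normalized mean magnitude spectrum forms a [0,1] frequency mask that later
shapes the diffusion noise covariance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import get_window
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

__all__ = [
    "SpectralFeatures", "StateModel", "spectral_features", "assign_states",
    "estimate_transitions", "build_masks", "fit_state_model",
]


@dataclass
class SpectralFeatures:
    """Per-window spectral signatures.

    ``features`` are log(1+m) magnitudes flattened across channels
    (N, K*C); ``magnitudes`` keeps the pre-log spectra (N, K, C) for mask
    construction.
    """

    features: np.ndarray
    magnitudes: np.ndarray
    fft_size: int
    stft_window: int
    stft_hop: int

    @property
    def n_bins(self):
        return self.fft_size // 2 + 1


@dataclass
class StateModel:
    """Everything the diffusion/generation stages need about latent regimes."""

    S: int
    centroids: np.ndarray                  # (S, D) in clustering feature space
    states: List[np.ndarray]               # per source sequence, window states
    transition: np.ndarray                 # (S, S) row-stochastic
    masks: np.ndarray                      # (S, K) in [0, 1]
    cluster_to_class: Optional[dict] = None
    class_state_occupancy: Optional[np.ndarray] = None  # (n_classes, S)
    pca_mean: Optional[np.ndarray] = None
    pca_components: Optional[np.ndarray] = None
    fft_size: int = 256
    stft_window: int = 32
    stft_hop: int = 8

    def states_for_class(self, label: int) -> np.ndarray:
        if self.cluster_to_class is None:
            return np.arange(self.S)
        sts = np.array([s for s, c in self.cluster_to_class.items() if c == label])
        if sts.size == 0:
            raise ValueError(f"class {label} has no mapped latent state")
        return sts

    def project(self, features: np.ndarray) -> np.ndarray:
        """Map raw feature vectors into the clustering space (PCA if fitted)."""
        if self.pca_components is None:
            return features
        return (features - self.pca_mean) @ self.pca_components.T

    # -- serialization: compressed array container with a JSON header ------
    def save(self, path):
        meta = {
            "S": int(self.S),
            "cluster_to_class": ({str(k): int(v) for k, v in self.cluster_to_class.items()}
                                 if self.cluster_to_class else None),
            "fft_size": self.fft_size, "stft_window": self.stft_window,
            "stft_hop": self.stft_hop, "n_state_seqs": len(self.states),
        }
        arrays = {"centroids": self.centroids, "transition": self.transition,
                  "masks": self.masks, "meta_json": np.frombuffer(
                      json.dumps(meta).encode(), dtype=np.uint8)}
        for i, s in enumerate(self.states):
            arrays[f"states_{i}"] = s
        if self.pca_components is not None:
            arrays["pca_mean"] = self.pca_mean
            arrays["pca_components"] = self.pca_components
        if self.class_state_occupancy is not None:
            arrays["class_state_occupancy"] = self.class_state_occupancy
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            states = [z[f"states_{i}"] for i in range(meta["n_state_seqs"])]
            c2c = meta["cluster_to_class"]
            return cls(
                S=meta["S"], centroids=z["centroids"], states=states,
                transition=z["transition"], masks=z["masks"],
                cluster_to_class={int(k): v for k, v in c2c.items()} if c2c else None,
                class_state_occupancy=(z["class_state_occupancy"]
                                       if "class_state_occupancy" in z else None),
                pca_mean=z["pca_mean"] if "pca_mean" in z else None,
                pca_components=z["pca_components"] if "pca_components" in z else None,
                fft_size=meta["fft_size"], stft_window=meta["stft_window"],
                stft_hop=meta["stft_hop"])


def frame_starts(window_length: int, frame: int, hop: int) -> np.ndarray:
    """Start indices of full STFT frames inside one window."""
    if frame > window_length:
        return np.array([0])
    return np.arange(0, window_length - frame + 1, hop)


def spectral_features(windows, fft_size: int = 256, stft_window: int = 32,
                      stft_hop: int = 8) -> SpectralFeatures:
    """Average log-magnitude STFT signature per window.

    ``windows`` is a WindowSet or an (N, l, C) array.  Frames of length
    ``stft_window`` at hop ``stft_hop`` are Hann-tapered, zero-padded to
    ``fft_size`` (K = fft_size/2+1 bins) and their magnitude spectra are
    averaged into one spectrum per window and channel.
    """
    w = getattr(windows, "windows", windows)
    w = np.asarray(w, dtype=np.float64)
    if w.ndim == 2:
        w = w[:, :, None]
    if w.shape[0] == 0:
        raise ValueError("empty window set")
    if fft_size & (fft_size - 1):
        warnings.warn(f"fft_size={fft_size} is not a power of two; proceeding")
    n, l, c = w.shape
    frame = min(stft_window, l)
    if frame > fft_size:
        raise ValueError("stft frame longer than fft_size")
    starts = frame_starts(l, frame, stft_hop)
    taper = get_window("hann", frame, fftbins=True)
    # (N, F, frame, C): all frames of all windows
    frames = np.stack([w[:, s:s + frame, :] for s in starts], axis=1)
    spec = np.abs(np.fft.rfft(frames * taper[None, None, :, None],
                              n=fft_size, axis=2))       # (N, F, K, C)
    mags = spec.mean(axis=1)                              # (N, K, C)
    feats = np.log1p(mags).reshape(n, -1)                 # (N, K*C)
    return SpectralFeatures(features=feats, magnitudes=mags, fft_size=fft_size,
                            stft_window=frame, stft_hop=stft_hop)


def assign_states(features: SpectralFeatures, S: int, seed: int,
                  iterations: int = 100, labels: Optional[np.ndarray] = None,
                  pca_dim: Optional[int] = None):
    """Cluster window signatures into S latent states.

    Returns ``(states, centroids, cluster_to_class, pca_mean, pca_components)``.
    k-means runs with a fixed seed and iteration cap, so assignment is
    deterministic; clusters emptied during iteration are re-seeded from the
    points farthest from their centers (scikit-learn's relocation rule).
    Majority-vote ties map to the lowest class id.
    """
    X = features.features if isinstance(features, SpectralFeatures) else np.asarray(features)
    if S < 2:
        raise ValueError("need at least S=2 latent states")
    if X.shape[0] < S:
        raise ValueError(f"{X.shape[0]} windows cannot fill S={S} states")
    pca_mean = pca_components = None
    if pca_dim is not None and pca_dim < X.shape[1]:
        pca = PCA(n_components=pca_dim, random_state=seed)
        X = pca.fit_transform(X)
        pca_mean, pca_components = pca.mean_, pca.components_
    km = KMeans(n_clusters=S, n_init=1, max_iter=iterations, random_state=seed)
    states = km.fit_predict(X)
    cluster_to_class = None
    if labels is not None:
        labels = np.asarray(labels)
        cluster_to_class = {}
        for s in range(S):
            member = labels[states == s]
            if member.size == 0:
                cluster_to_class[s] = int(labels.min())
                continue
            vals, counts = np.unique(member, return_counts=True)
            cluster_to_class[s] = int(vals[counts == counts.max()].min())
    return states, km.cluster_centers_, cluster_to_class, pca_mean, pca_components


def estimate_transitions(state_seqs: Sequence[np.ndarray], S: int,
                         smoothing: float = 1e-3) -> np.ndarray:
    """Empirical first-order transition matrix with pseudocount smoothing.

    P[i, j] = (count(i->j) + eps) / sum_j (count(i->j) + eps).  Transitions
    are counted only within a source sequence.  A state never occupied as a
    predecessor gets a uniform row.
    """
    if isinstance(state_seqs, np.ndarray) and state_seqs.ndim == 1:
        state_seqs = [state_seqs]
    counts = np.zeros((S, S))
    n_pairs = 0
    for seq in state_seqs:
        seq = np.asarray(seq, dtype=int)
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no adjacent state pairs to estimate transitions from")
    counts = counts + smoothing
    rows = counts.sum(axis=1)
    P = np.empty_like(counts)
    for i in range(S):
        if rows[i] <= 0:
            P[i] = 1.0 / S          # never-occupied state: uniform convention
        else:
            P[i] = counts[i] / rows[i]
    return P


def build_masks(magnitudes: np.ndarray, states: np.ndarray, S: int) -> np.ndarray:
    """Per-state spectral masks: min-max normalized mean magnitude spectra.

    ``magnitudes`` are pre-log spectra (N, K, C); multichannel spectra are
    averaged across channels to one length-K template.  Empty states and
    states with a constant mean spectrum fall back to an all-ones
    (isotropic) mask.
    """
    mags = np.asarray(magnitudes, dtype=np.float64)
    if mags.ndim == 2:
        mags = mags[:, :, None]
    states = np.asarray(states, dtype=int)
    K = mags.shape[1]
    masks = np.ones((S, K))
    for s in range(S):
        member = mags[states == s]
        if member.shape[0] == 0:
            log.info("state %d has no member windows; using isotropic mask", s)
            continue
        m = member.mean(axis=(0, 2))     # mean over windows and channels
        lo, hi = m.min(), m.max()
        if hi - lo < 1e-15:
            log.info("state %d has a constant mean spectrum; isotropic mask", s)
            continue
        masks[s] = (m - lo) / (hi - lo)
    return masks


def fit_state_model(window_sets, S: int, seed: int, fft_size: int = 256,
                    stft_window: int = 32, stft_hop: int = 8,
                    iterations: int = 100, pca_dim: Optional[int] = None,
                    smoothing: float = 1e-3, n_classes: Optional[int] = None) -> StateModel:
    """Full regime-discovery pipeline over a list of WindowSets."""
    all_w = np.concatenate([ws.windows for ws in window_sets], axis=0)
    feats = spectral_features(all_w, fft_size, stft_window, stft_hop)
    labels = np.concatenate([
        np.full(ws.n_windows, -1 if ws.source_label is None else ws.source_label)
        for ws in window_sets])
    use_labels = labels if (labels >= 0).all() else None
    states, centroids, c2c, pmean, pcomp = assign_states(
        feats, S, seed, iterations, labels=use_labels, pca_dim=pca_dim)
    # split flat state vector back into per-sequence paths
    splits = np.cumsum([ws.n_windows for ws in window_sets])[:-1]
    state_seqs = np.split(states, splits)
    P = estimate_transitions(state_seqs, S, smoothing)
    masks = build_masks(feats.magnitudes, states, S)
    occupancy = None
    if use_labels is not None:
        classes = np.unique(use_labels) if n_classes is None else np.arange(n_classes)
        occupancy = np.zeros((len(classes), S))
        for ci, c in enumerate(classes):
            member = states[use_labels == c]
            for s in member:
                occupancy[ci, s] += 1
            tot = occupancy[ci].sum()
            if tot > 0:
                occupancy[ci] /= tot
    return StateModel(S=S, centroids=centroids, states=state_seqs, transition=P,
                      masks=masks, cluster_to_class=c2c,
                      class_state_occupancy=occupancy,
                      pca_mean=pmean, pca_components=pcomp, fft_size=fft_size,
                      stft_window=stft_window, stft_hop=stft_hop)
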