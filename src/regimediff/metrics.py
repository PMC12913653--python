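"""The four evaluation metrics with the multi-seed mean ± sd protocol.

* FID: Fréchet distance between Gaussians fitted to real and generated
  embedding clouds from the frozen recurrent encoder.
* DTW: mean best-alignment cost of each generated sequence to its nearest
  real sequence of the same class (Euclidean local cost, no band).
* CCA (class consistency accuracy): fraction of generated samples whose
  predicted label matches the intended one, scored by a classifier trained
  on real data only and gated on held-out real accuracy.
* SD (spectral distance): mean Euclidean distance between sum-normalized
  power spectra, each generated sequence against the mean normalized
  spectrum of its class's real set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import scipy.linalg
from numba import njit

__all__ = ["GateError", "MetricsReport", "fid", "fid_from_embeddings",
           "frechet_distance", "dtw", "dtw_score", "cca_score",
           "spectral_distance", "multi_seed_report"]


class GateError(RuntimeError):
    """The CCA classifier failed its real-data accuracy gate."""


# -- FID -------------------------------------------------------------------

def frechet_distance(mu1, sigma1, mu2, sigma2, ridge: float = 1e-6) -> float:
    """||mu1-mu2||^2 + tr(S1 + S2 - 2 (S1 S2)^{1/2}) with ridge fallback."""
    mu1, mu2 = np.asarray(mu1), np.asarray(mu2)
    sigma1, sigma2 = np.atleast_2d(sigma1), np.atleast_2d(sigma2)
    diff = float(np.sum((mu1 - mu2) ** 2))
    cov_sqrt, _ = scipy.linalg.sqrtm(sigma1 @ sigma2, disp=False)
    if not np.all(np.isfinite(cov_sqrt)):
        eye = np.eye(sigma1.shape[0])
        cov_sqrt, _ = scipy.linalg.sqrtm((sigma1 + ridge * eye) @ (sigma2 + ridge * eye),
                                         disp=False)
    if np.iscomplexobj(cov_sqrt):
        cov_sqrt = cov_sqrt.real
    val = diff + float(np.trace(sigma1) + np.trace(sigma2) - 2.0 * np.trace(cov_sqrt))
    return max(val, 0.0)


def fid_from_embeddings(emb_real: np.ndarray, emb_gen: np.ndarray) -> float:
    if len(emb_real) < 2 or len(emb_gen) < 2:
        raise ValueError("need at least 2 samples per set to fit a Gaussian")
    mu1, mu2 = emb_real.mean(0), emb_gen.mean(0)
    s1 = np.cov(emb_real, rowvar=False)
    s2 = np.cov(emb_gen, rowvar=False)
    return frechet_distance(mu1, s1, mu2, s2)


def fid(real_set, gen_set, encoder) -> float:
    """Fréchet distance in the encoder's embedding space."""
    return fid_from_embeddings(encoder.embed(np.asarray(real_set)),
                               encoder.embed(np.asarray(gen_set)))


# -- DTW -------------------------------------------------------------------

@njit(cache=False)
def _dtw_cost(a, b):
    n, m = a.shape[0], b.shape[0]
    big = 1e300
    D = np.full((n + 1, m + 1), big)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = 0.0
            for k in range(a.shape[1]):
                d = a[i - 1, k] - b[j - 1, k]
                c += d * d
            c = np.sqrt(c)
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D[n, m]


def _to2d(x):
    x = np.asarray(x, dtype=np.float64)
    return x[:, None] if x.ndim == 1 else x


def dtw(a, b) -> float:
    """Minimum-cost monotone alignment (Euclidean local cost, no band)."""
    return float(_dtw_cost(np.ascontiguousarray(_to2d(a)),
                           np.ascontiguousarray(_to2d(b))))


def dtw_score(real_set, gen_set, real_labels=None, gen_labels=None,
              pairing: str = "nearest", rng: Optional[np.random.Generator] = None) -> float:
    """Mean DTW of each generated sequence to its nearest same-class real one.

    ``pairing='random'`` instead matches each generated sequence to one
    random class-matched real sequence.
    """
    real = [_to2d(r) for r in real_set]
    gen = [_to2d(g) for g in gen_set]
    if not real or not gen:
        raise ValueError("empty sequence set")
    rl = np.zeros(len(real), dtype=int) if real_labels is None else np.asarray(real_labels)
    gl = np.zeros(len(gen), dtype=int) if gen_labels is None else np.asarray(gen_labels)
    rng = rng or np.random.default_rng(0)
    costs = []
    for g, lab in zip(gen, gl):
        pool = [r for r, rlab in zip(real, rl) if rlab == lab]
        if not pool:
            warnings.warn(f"class {lab} absent from the real set; skipping")
            continue
        if pairing == "random":
            costs.append(dtw(g, pool[rng.integers(len(pool))]))
        else:
            costs.append(min(dtw(g, r) for r in pool))
    if not costs:
        raise ValueError("no class-matched pairs to score")
    return float(np.mean(costs))


# -- CCA -------------------------------------------------------------------

def cca_score(gen_set, intended_labels, classifier, gate: float = 0.85) -> float:
    """Fraction of generated samples classified as their intended class."""
    acc = getattr(classifier, "holdout_accuracy", None)
    if acc is None or acc < gate:
        raise GateError(
            f"classifier held-out accuracy {acc} below the {gate} gate; refusing to score")
    pred = classifier.predict(np.asarray(gen_set))
    return float(np.mean(pred == np.asarray(intended_labels)))


# -- Spectral distance -----------------------------------------------------

def _norm_power_spectrum(x, nfft):
    """Sum-normalized power spectrum; uniform convention for zero energy."""
    x = _to2d(x)[:nfft]
    p = np.abs(np.fft.rfft(x, n=nfft, axis=0)) ** 2
    p = p.mean(axis=1)                       # average channels
    tot = p.sum()
    if tot <= 0:
        return np.full(len(p), 1.0 / len(p))
    return p / tot


def spectral_distance(real_set, gen_set, real_labels=None, gen_labels=None,
                      nfft: Optional[int] = None, per_sequence: bool = False) -> float:
    """Class-matched distance between mean normalized power spectra.

    Per class, the mean sum-normalized power spectrum of the generated set
    is compared with the class-mean real spectrum; distances are averaged
    over classes weighted by generated counts.  This makes identical sets
    score exactly 0.  ``per_sequence=True`` instead scores each generated
    sequence against its class-mean real spectrum (nonzero even for
    identical sets, since individual spectra differ from the class mean).
    """
    real = [_to2d(r) for r in real_set]
    gen = [_to2d(g) for g in gen_set]
    if not real or not gen:
        raise ValueError("empty sequence set")
    rl = np.zeros(len(real), dtype=int) if real_labels is None else np.asarray(real_labels)
    gl = np.zeros(len(gen), dtype=int) if gen_labels is None else np.asarray(gen_labels)
    nfft = nfft or max(len(r) for r in real)
    class_means = {}
    for c in np.unique(rl):
        specs = np.stack([_norm_power_spectrum(r, nfft) for r, lab in zip(real, rl) if lab == c])
        class_means[c] = specs.mean(axis=0)
    dists, weights = [], []
    for c in np.unique(gl):
        if c not in class_means:
            warnings.warn(f"class {c} absent from the real set; skipping")
            continue
        specs = np.stack([_norm_power_spectrum(g, nfft) for g, lab in zip(gen, gl) if lab == c])
        if per_sequence:
            dists.append(np.linalg.norm(specs - class_means[c], axis=1).mean())
        else:
            dists.append(np.linalg.norm(specs.mean(axis=0) - class_means[c]))
        weights.append(len(specs))
    if not dists:
        raise ValueError("no class-matched pairs to score")
    return float(np.average(dists, weights=weights))


# -- multi-seed protocol ---------------------------------------------------

@dataclass
class MetricsReport:
    """Mean ± sd over the configured seeds for each metric."""

    seeds: List[int]
    metrics: dict = field(default_factory=dict)   # name -> {mean, sd, values}
    encoder_fingerprint: str = ""
    classifier_fingerprint: str = ""

    def add(self, name: str, values: Sequence[float]):
        values = [float(v) for v in values]
        if len(values) != len(self.seeds):
            raise ValueError("per-seed value count must match the seed list")
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        self.metrics[name] = {"mean": float(np.mean(values)), "sd": sd, "values": values}

    def to_json(self, path=None):
        payload = {"seeds": self.seeds, "metrics": self.metrics,
                   "encoder_fingerprint": self.encoder_fingerprint,
                   "classifier_fingerprint": self.classifier_fingerprint}
        text = json.dumps(payload, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def table(self) -> str:
        lines = [f"{'metric':8s} {'mean':>10s} {'sd':>10s}"]
        for name, m in self.metrics.items():
            lines.append(f"{name:8s} {m['mean']:10.4f} {m['sd']:10.4f}")
        return "\n".join(lines)


def multi_seed_report(generate_fn: Callable[[int], tuple], real_set, real_labels,
                      encoder, classifier, seeds: Sequence[int],
                      gate: float = 0.85) -> MetricsReport:
    """Run the full metric suite once per seed.

    ``generate_fn(seed)`` must return ``(gen_set, gen_labels)``.
    """
    report = MetricsReport(seeds=list(seeds),
                           encoder_fingerprint=getattr(encoder, "fingerprint", ""),
                           classifier_fingerprint=getattr(classifier, "fingerprint", ""))
    vals = {"fid": [], "dtw": [], "cca": [], "sd": []}
    for seed in seeds:
        gen_set, gen_labels = generate_fn(seed)
        vals["fid"].append(fid(real_set, gen_set, encoder))
        vals["dtw"].append(dtw_score(real_set, gen_set, real_labels, gen_labels))
        vals["cca"].append(cca_score(gen_set, gen_labels, classifier, gate=gate))
        vals["sd"].append(spectral_distance(real_set, gen_set, real_labels, gen_labels))
    for name, v in vals.items():
        report.add(name, v)
    return report
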