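"""Learned sequence embeddings for evaluation.

Two small networks trained on the real training split only:

* ``RecurrentEncoder`` -- an Elman recurrence whose final hidden state is the
  fixed-length embedding used by the Fréchet distance; trained as a
  classifier with a fixed seed and epoch budget, then frozen.  The report
  fingerprints the trained weights so runs are comparable.
* ``ConvClassifier`` -- a three-layer strided 1-D CNN used for class
  consistency accuracy; it must clear a held-out accuracy gate before it is
  allowed to score generated data.
"""

from __future__ import annotations

import hashlib

import numpy as np

from . import _engine as E
from . import nn
from ._engine import Tensor

__all__ = ["RecurrentEncoder", "ConvClassifier", "train_encoder", "train_classifier"]


def _one_hot(labels, k):
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    lse = E.log(E.sum_(E.exp(logits), axis=1, keepdims=True))
    logp = E.add(logits, E.mul(lse, -1.0))
    return E.mul(E.mean(E.sum_(E.mul(logp, Tensor(onehot)), axis=1)), -1.0)


def _as_batch(x):
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


class RecurrentEncoder(nn.Module):
    def __init__(self, channels: int, n_classes: int, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.rnn = nn.ElmanRNN(channels, hidden, rng)
        self.head = nn.Linear(hidden, n_classes, rng)
        self.hidden = hidden

    def embed(self, x) -> np.ndarray:
        with E.no_grad():
            return self.rnn(Tensor(_as_batch(x))).data

    def logits(self, x) -> Tensor:
        return self.head(self.rnn(x if isinstance(x, Tensor) else Tensor(_as_batch(x))))

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for p in self.params():
            h.update(p.data.tobytes())
        return h.hexdigest()[:16]


class ConvClassifier(nn.Module):
    def __init__(self, channels: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.c1 = nn.Conv1d(channels, 16, 5, rng, stride=2, padding=2)
        self.c2 = nn.Conv1d(16, 32, 5, rng, stride=2, padding=2)
        self.c3 = nn.Conv1d(32, 32, 5, rng, stride=2, padding=2)
        self.head = nn.Linear(32, n_classes, rng)
        self.holdout_accuracy = None   # set by the training gate

    def logits(self, x) -> Tensor:
        xt = x if isinstance(x, Tensor) else Tensor(_as_batch(x))
        h = E.transpose(xt, (0, 2, 1))
        for conv in (self.c1, self.c2, self.c3):
            h = E.leaky_relu(conv(h), 0.2)
        return self.head(E.mean(h, axis=2))

    def predict(self, x) -> np.ndarray:
        with E.no_grad():
            return np.argmax(self.logits(x).data, axis=1)

    def accuracy(self, x, labels) -> float:
        return float(np.mean(self.predict(x) == np.asarray(labels)))

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for p in self.params():
            h.update(p.data.tobytes())
        return h.hexdigest()[:16]


def _train(model, x, labels, n_classes, epochs, lr, batch, rng):
    onehot_all = _one_hot(np.asarray(labels), n_classes)
    n = len(x)
    opt = nn.Adam(model.params(), lr=lr, betas=(0.9, 0.999))
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            loss = _cross_entropy(model.logits(x[idx]), onehot_all[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def train_encoder(sequences, labels, n_classes: int, seed: int = 0,
                  epochs: int = 30, lr: float = 5e-3, batch: int = 64) -> RecurrentEncoder:
    """Fit the Fréchet embedding network on the real training split."""
    x = _as_batch(sequences)
    rng = np.random.default_rng(seed + 1)
    enc = RecurrentEncoder(x.shape[2], n_classes, seed=seed)
    return _train(enc, x, labels, n_classes, epochs, lr, batch, rng)


def train_classifier(sequences, labels, n_classes: int, seed: int = 0,
                     epochs: int = 60, lr: float = 5e-3, batch: int = 64,
                     holdout=None) -> ConvClassifier:
    """Fit the CCA gate classifier; records held-out accuracy when given."""
    x = _as_batch(sequences)
    rng = np.random.default_rng(seed + 2)
    clf = ConvClassifier(x.shape[2], n_classes, seed=seed)
    _train(clf, x, labels, n_classes, epochs, lr, batch, rng)
    if holdout is not None:
        hx, hy = holdout
        clf.holdout_accuracy = clf.accuracy(_as_batch(hx), hy)
    return clf
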