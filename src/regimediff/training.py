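"""Composite-objective adversarial training.

One iteration: sample a batch of sequences, take their precomputed
normalized windows and latent states, encode each window to z_0, run the
state-masked forward diffusion, denoise with the reverse generator, decode,
overlap-add into full sequences, then optimize

    L = L_adv + lambda_spec * spectral MSE
             + lambda_KL  * KL(P_theta || P_hat)
             + lambda_rec * MSE(z_0, z_hat_0)

with WGAN-GP critic updates interleaved (several critic steps per generator
step).  Checkpoints are selected by minimum validation FID, which doubles
as the early-stopping criterion.  Ablation switches: ``no_mask`` (isotropic
noise), ``no_markov`` (uniform state sampling, no transition KL),
``no_diff`` (no forward/reverse chain; a plain GAN on latents), ``no_adv``
(no critic).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np

from . import _engine as E
from . import nn
from ._engine import Tensor
from .diffusion import make_schedule
from .discriminator import Critic
from .embedding import train_encoder
from .generator import ReverseGenerator, generate_sequence
from .metrics import fid as fid_metric
from .metrics import spectral_distance
from .spectral_states import StateModel, fit_state_model, frame_starts
from .windowing import TimeSeries, segment

__all__ = ["LossWeights", "TrainConfig", "TrainState", "TrainingDiverged",
           "spectral_loss", "transition_kl", "adversarial_losses", "train"]


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; carries a diagnostic dump."""

    def __init__(self, iteration, components):
        self.iteration, self.components = iteration, components
        super().__init__(f"non-finite loss at iteration {iteration}: {components}")


@dataclass
class LossWeights:
    lambda_spec: float = 1.0
    lambda_kl: float = 0.1
    lambda_rec: float = 1.0
    gp_coefficient: float = 10.0
    critic_steps: int = 3

    def __post_init__(self):
        for name in ("lambda_spec", "lambda_kl", "lambda_rec", "gp_coefficient"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrainConfig:
    l: int = 64
    h: int = 16
    S: int = 8
    T: int = 50
    fft_size: int = 256
    stft_window: int = 32
    stft_hop: int = 8
    d: int = 64
    batch: int = 64
    lr: float = 1e-4
    iterations: int = 5000
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    eval_interval: int = 250
    log_interval: int = 50
    patience: int = 10
    val_fraction: float = 0.2
    kl_temperature: float = 1.0
    detach_kl: bool = False
    pca_dim: Optional[int] = None
    kmeans_iterations: int = 100
    transition_smoothing: float = 1e-3
    # calibrated so alpha_bar_T ~ 0 at T=50: z_T is genuinely noise-dominated
    beta_min: float = 1e-4
    beta_max: float = 1e-1
    n_eval_sequences: int = 16
    encoder_epochs: int = 30
    critic_channels: tuple = (32, 64, 64)
    no_mask: bool = False
    no_markov: bool = False
    no_diff: bool = False
    no_adv: bool = False
    checkpoint_dir: Optional[str] = None
    log_dir: Optional[str] = None


@dataclass
class TrainState:
    iteration: int
    best_fid: float
    checkpoint_path: Optional[str]
    log: List[dict]
    eval_log: List[dict]
    generator: ReverseGenerator
    critic: Optional[Critic]
    state_model: StateModel
    class_denorm: dict
    config: TrainConfig
    sd_trace: List[float] = field(default_factory=list)
    checkpoint_metrics: Optional[dict] = None   # FID/SD at the selected checkpoint


# -- loss operations -------------------------------------------------------

def _magnitudes_t(x: Tensor, n: int, axis_len: int) -> Tensor:
    """|FFT| along the time axis of (B, L, C), as (B, C, K)."""
    xt = E.transpose(x, (0, 2, 1))
    r = E.rfft_real(xt, n)
    i = E.rfft_imag(xt, n)
    return E.sqrt(E.add(E.add(E.square(r), E.square(i)), 1e-24))


def spectral_loss(x_hat, x) -> Tensor:
    """Mean squared error between full-transform magnitude spectra.

    Inputs are (B, L, C) (tensor or array); lengths are truncated to the
    common covered extent.
    """
    xh = x_hat if isinstance(x_hat, Tensor) else Tensor(np.asarray(x_hat, dtype=np.float64))
    xr = np.asarray(x.data if isinstance(x, Tensor) else x, dtype=np.float64)
    if xh.ndim == 2:
        xh = E.reshape(xh, (*xh.shape, 1))
    if xr.ndim == 2:
        xr = xr[:, :, None]
    L = min(xh.shape[1], xr.shape[1])
    if abs(xh.shape[1] - xr.shape[1]) > max(xh.shape[1], xr.shape[1]) // 2:
        raise ValueError("sequence lengths differ beyond overlap handling")
    xh = E.getitem(xh, (slice(None), slice(0, L), slice(None)))
    mh = _magnitudes_t(xh, L, L)
    mr = np.abs(np.fft.rfft(xr[:, :L].transpose(0, 2, 1), n=L, axis=-1))
    return E.mean(E.square(E.add(mh, E.mul(Tensor(mr), -1.0))))


def _stft_features_t(x: Tensor, fft_size: int, frame: int, hop: int) -> Tensor:
    """Differentiable copy of the window spectral signature (B, K*C)."""
    from scipy.signal import get_window
    B, l, C = x.shape
    frame = min(frame, l)
    starts = frame_starts(l, frame, hop)
    taper = Tensor(get_window("hann", frame, fftbins=True))
    acc = None
    for s in starts:
        seg = E.transpose(E.getitem(x, (slice(None), slice(s, s + frame), slice(None))),
                          (0, 2, 1))
        seg = E.mul(seg, taper)
        r = E.rfft_real(seg, fft_size)
        i = E.rfft_imag(seg, fft_size)
        mag = E.sqrt(E.add(E.add(E.square(r), E.square(i)), 1e-24))
        acc = mag if acc is None else E.add(acc, mag)
    feats = E.log1p(E.mul(acc, 1.0 / len(starts)))          # (B, C, K)
    return E.reshape(E.transpose(feats, (0, 2, 1)), (B, -1))


def transition_kl(gen_windows, state_model: StateModel, temperature: float = 1.0,
                  n_per_seq: Optional[int] = None, eps: float = 1e-6,
                  detach: bool = False) -> Tensor:
    """KL(P_theta || P_hat) from soft state assignments of generated windows.

    Windows are soft-assigned to the k-means centroids with
    softmax(-distance^2 / temperature); expected adjacent-pair counts within
    each generated sequence induce P_theta.  Both matrices are
    eps-smoothed.  Differentiable unless ``detach``.
    """
    x = gen_windows if isinstance(gen_windows, Tensor) else Tensor(
        np.asarray(gen_windows, dtype=np.float64))
    if x.ndim == 2:
        x = E.reshape(x, (*x.shape, 1))
    Bw = x.shape[0]
    N = n_per_seq or Bw
    if N < 2:
        raise ValueError("need at least 2 windows per generated sequence")
    ctx = E.no_grad() if detach else None
    if ctx:
        ctx.__enter__()
    try:
        feats = _stft_features_t(x, state_model.fft_size, state_model.stft_window,
                                 state_model.stft_hop)
        if state_model.pca_components is not None:
            feats = E.matmul(E.add(feats, Tensor(-state_model.pca_mean)),
                             Tensor(state_model.pca_components.T))
        C = state_model.centroids
        d2 = E.add(E.add(E.sum_(E.square(feats), axis=1, keepdims=True),
                         E.mul(E.matmul(feats, Tensor(C.T)), -2.0)),
                   Tensor((C ** 2).sum(axis=1)[None, :]))
        Q = E.softmax(E.mul(d2, -1.0 / temperature), axis=1)   # (Bw, S)
        S = state_model.S
        nseq = Bw // N
        Q3 = E.reshape(Q, (nseq, N, S))
        Qp = E.reshape(E.getitem(Q3, (slice(None), slice(0, N - 1), slice(None))),
                       (nseq * (N - 1), S))
        Qn = E.reshape(E.getitem(Q3, (slice(None), slice(1, N), slice(None))),
                       (nseq * (N - 1), S))
        counts = E.add(E.matmul(E.transpose(Qp, (1, 0)), Qn), eps)
        P_theta = E.mul(counts, E.power(E.sum_(counts, axis=1, keepdims=True), -1.0))
        P_hat = state_model.transition + eps
        P_hat = P_hat / P_hat.sum(axis=1, keepdims=True)
        ratio = E.mul(P_theta, Tensor(1.0 / P_hat))
        return E.sum_(E.mul(P_theta, E.log(ratio)))
    finally:
        if ctx:
            ctx.__exit__()


def _critic_loss(real_arr, fake_arr, critic, gp_coefficient, rng):
    """Critic-side WGAN-GP loss on detached batches (no generator graph)."""
    w_term = E.add(E.mean(critic(Tensor(fake_arr))),
                   E.mul(E.mean(critic(Tensor(real_arr))), -1.0))
    u = rng.uniform(size=(real_arr.shape[0], 1, 1))
    x_tilde = Tensor(u * real_arr + (1 - u) * fake_arr, requires_grad=True)
    g, = E.grad_of(E.sum_(critic(x_tilde)), [x_tilde], create_graph=True)
    norms = E.sqrt(E.add(E.sum_(E.square(g), axis=(1, 2)), 1e-12))
    penalty = E.mean(E.square(E.add(norms, -1.0)))
    return E.add(w_term, E.mul(penalty, gp_coefficient))


def adversarial_losses(real_batch, fake_batch, critic: Critic,
                       gp_coefficient: float = 10.0,
                       rng: Optional[np.random.Generator] = None):
    """WGAN-GP losses.

    Returns ``(critic_loss, generator_adv_loss)``; the critic loss includes
    the gradient penalty at uniform interpolates, the generator loss is
    -mean(score(fake)) and keeps the generator graph when ``fake_batch`` is
    a tensor.
    """
    rng = rng or np.random.default_rng(0)
    fake_t = fake_batch if isinstance(fake_batch, Tensor) else Tensor(
        np.asarray(fake_batch, dtype=np.float64))
    real_arr = np.asarray(real_batch.data if isinstance(real_batch, Tensor) else real_batch,
                          dtype=np.float64)
    if real_arr.ndim == 2:
        real_arr = real_arr[:, :, None]
    fake_arr = fake_t.data if fake_t.ndim == 3 else fake_t.data[:, :, None]
    w_fake = E.mean(critic(fake_t))
    w_real = E.mean(critic(Tensor(real_arr)))
    u = rng.uniform(size=(real_arr.shape[0], 1, 1))
    x_tilde = Tensor(u * real_arr + (1 - u) * fake_arr, requires_grad=True)
    score = E.sum_(critic(x_tilde))
    g, = E.grad_of(score, [x_tilde], create_graph=True)
    norms = E.sqrt(E.add(E.sum_(E.square(g), axis=(1, 2)), 1e-12))
    penalty = E.mean(E.square(E.add(norms, -1.0)))
    critic_loss = E.add(E.add(E.mean(critic(Tensor(fake_arr))), E.mul(w_real, -1.0)),
                        E.mul(penalty, gp_coefficient))
    gen_adv = E.mul(w_fake, -1.0)
    return critic_loss, gen_adv


# -- helpers ---------------------------------------------------------------

def _batched_state_noise(masks_rows: np.ndarray, d: int, fft_size: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Mask-shaped noise for a batch of windows, one mask row per window."""
    white = rng.standard_normal((masks_rows.shape[0], fft_size))
    spec = np.fft.rfft(white, axis=-1) * np.sqrt(masks_rows)
    return np.fft.irfft(spec, n=fft_size, axis=-1)[:, :d]


def _aggregate_t(windows: Tensor, n_per_seq: int, l: int, h: int) -> Tensor:
    """Differentiable overlap-add: (B*N, l, C) -> (B, L_cov, C)."""
    BN, _, C = windows.shape
    B = BN // n_per_seq
    L_cov = (n_per_seq - 1) * h + l
    counts = np.zeros(L_cov)
    for n in range(n_per_seq):
        counts[n * h:n * h + l] += 1
    w4 = E.reshape(windows, (B, n_per_seq, l, C))
    acc = None
    for n in range(n_per_seq):
        seg = E.getitem(w4, (slice(None), n, slice(None), slice(None)))
        placed = E.unslice(seg, (slice(None), slice(n * h, n * h + l), slice(None)),
                           (B, L_cov, C))
        acc = placed if acc is None else E.add(acc, placed)
    return E.mul(acc, Tensor(1.0 / counts[None, :, None]))


def _stratified_split(labels: np.ndarray, frac: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        members = members[rng.permutation(len(members))]
        n_val = max(1, int(round(frac * len(members))))
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


# -- the training loop -----------------------------------------------------

def train(dataset: List[TimeSeries], config: TrainConfig,
          encoder=None, state_model: Optional[StateModel] = None) -> TrainState:
    """Run the full training procedure on a labeled sequence collection."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = np.array([ts.label for ts in dataset])
    n_classes = len(np.unique(labels))
    lengths = {ts.length for ts in dataset}
    if len(lengths) != 1:
        raise ValueError("training requires equal-length sequences")
    channels = dataset[0].channels

    tr_idx, va_idx = _stratified_split(labels, cfg.val_fraction, rng)
    train_seqs = [dataset[i] for i in tr_idx]
    val_seqs = [dataset[i] for i in va_idx]

    window_sets = [segment(ts, cfg.l, cfg.h, normalize=True) for ts in train_seqs]
    n_per_seq = window_sets[0].n_windows
    if state_model is None:
        state_model = fit_state_model(
            window_sets, cfg.S, cfg.seed, cfg.fft_size, cfg.stft_window,
            cfg.stft_hop, cfg.kmeans_iterations, cfg.pca_dim,
            cfg.transition_smoothing, n_classes=n_classes)
    W_all = np.stack([ws.windows for ws in window_sets])         # (B, N, l, C)
    S_all = np.stack(state_model.states) if len(state_model.states) == len(window_sets) \
        else np.stack([np.zeros(n_per_seq, dtype=int)] * len(window_sets))
    R_agg = np.stack([_aggregate_t(Tensor(ws.windows), ws.n_windows, cfg.l, cfg.h).data[0]
                      for ws in window_sets])                    # (B, L_cov, C)
    train_labels = np.array([ts.label for ts in train_seqs])

    class_denorm = {}
    for c in np.unique(train_labels):
        sel = [ws for ws, lab in zip(window_sets, train_labels) if lab == c]
        class_denorm[int(c)] = (
            np.mean([ws.norm_mean.mean(axis=0) for ws in sel], axis=0),
            np.mean([ws.norm_std.mean(axis=0) for ws in sel], axis=0))

    gen = ReverseGenerator(S=cfg.S, l=cfg.l, channels=channels, d=cfg.d,
                       fft_size=cfg.fft_size, seed=cfg.seed + 1)
    critic = None if cfg.no_adv else Critic(channels=channels,
                                            time_channels=tuple(cfg.critic_channels),
                                            seed=cfg.seed + 2)
    opt_g = nn.Adam(gen.params(), lr=cfg.lr, betas=(0.5, 0.9))
    opt_c = nn.Adam(critic.params(), lr=cfg.lr, betas=(0.5, 0.9)) if critic else None

    schedule = make_schedule(0 if cfg.no_diff else cfg.T, cfg.beta_min, cfg.beta_max)
    masks_eff = np.ones_like(state_model.masks) if cfg.no_mask else state_model.masks
    kl_weight = 0.0 if cfg.no_markov else cfg.weights.lambda_kl

    if encoder is None:
        encoder = train_encoder(
            np.stack([ts.values for ts in train_seqs]), train_labels, n_classes,
            seed=cfg.seed, epochs=cfg.encoder_epochs)
    val_values = [ts.values for ts in val_seqs]
    val_labels = [ts.label for ts in val_seqs]

    eval_rng = np.random.default_rng(cfg.seed + 10)
    best_fid, best_params, best_iter = np.inf, None, -1
    eval_log, loss_log, sd_trace = [], [], []
    evals_since_best = 0

    def compute_eval(iteration):
        per_class = max(1, cfg.n_eval_sequences // n_classes)
        gen_vals, gen_labs = [], []
        for c in sorted(class_denorm):
            for _ in range(per_class):
                gs = generate_sequence(c, n_per_seq, state_model, gen, schedule,
                                       cfg.h, eval_rng, denorm=class_denorm[c],
                                       no_markov=cfg.no_markov, no_mask=cfg.no_mask)
                gen_vals.append(gs.values)
                gen_labs.append(c)
        L_cov = gen_vals[0].shape[0]
        val_trim = [v[:L_cov] for v in val_values]
        cur_fid = fid_metric(np.stack(val_trim), np.stack(gen_vals), encoder)
        cur_sd = spectral_distance(val_trim, gen_vals, val_labels, gen_labs)
        return {"iteration": iteration, "fid": cur_fid, "sd": cur_sd}

    def run_eval(iteration):
        nonlocal best_fid, best_params, best_iter, evals_since_best
        row = compute_eval(iteration)
        eval_log.append(row)
        sd_trace.append(row["sd"])
        if row["fid"] < best_fid:
            best_fid, best_iter = row["fid"], iteration
            best_params = [p.copy() for p in gen.state_arrays()]
            evals_since_best = 0
        else:
            evals_since_best += 1

    run_eval(0)
    B_total = len(train_seqs)
    log_fh = None
    if cfg.log_dir:
        os.makedirs(cfg.log_dir, exist_ok=True)
        with open(os.path.join(cfg.log_dir, "config.json"), "w") as fh:
            json.dump({**asdict(cfg)}, fh, indent=2, default=str)
        log_fh = open(os.path.join(cfg.log_dir, "train_log.jsonl"), "w")

    try:
        for it in range(1, cfg.iterations + 1):
            idx = rng.choice(B_total, size=min(cfg.batch, B_total), replace=False)
            w = W_all[idx].reshape(-1, cfg.l, channels)
            st = S_all[idx].reshape(-1)
            real_seq = R_agg[idx]

            z0 = gen.encode(w)
            if cfg.no_diff:
                z_hat0 = Tensor(_batched_state_noise(masks_eff[st], cfg.d,
                                                     cfg.fft_size, rng))
                rec = Tensor(0.0)
            else:
                with E.no_grad():
                    zt = z0.data.copy()
                    for t in range(schedule.T):
                        eps = _batched_state_noise(masks_eff[st], cfg.d,
                                                   cfg.fft_size, rng)
                        zt = np.sqrt(schedule.alpha[t]) * zt + \
                            np.sqrt(1 - schedule.alpha[t]) * eps
                z_hat0 = gen.reverse_chain(zt, st, schedule)
                rec = E.mean(E.square(E.add(z0, E.mul(z_hat0, -1.0))))
            fake_w = gen.decode(z_hat0)
            fake_seq = _aggregate_t(fake_w, n_per_seq, cfg.l, cfg.h)

            if critic is not None:
                fake_const = fake_seq.data
                for _ in range(cfg.weights.critic_steps):
                    c_loss = _critic_loss(real_seq, fake_const, critic,
                                          cfg.weights.gp_coefficient, rng)
                    opt_c.zero_grad()
                    c_loss.backward()
                    opt_c.step()
                adv = E.mul(E.mean(critic(fake_seq)), -1.0)
            else:
                c_loss, adv = Tensor(0.0), Tensor(0.0)

            spec = spectral_loss(fake_seq, real_seq)
            if kl_weight > 0:
                kl = transition_kl(fake_w, state_model, cfg.kl_temperature,
                                   n_per_seq, detach=cfg.detach_kl)
            else:
                kl = Tensor(0.0)
            total = E.add(E.add(adv, E.mul(spec, cfg.weights.lambda_spec)),
                          E.add(E.mul(kl, kl_weight),
                                E.mul(rec, cfg.weights.lambda_rec)))
            comp = {"iteration": it, "total": total.item(), "adv": adv.item(),
                    "spec": spec.item(), "kl": kl.item(), "rec": rec.item(),
                    "critic": c_loss.item() if critic is not None else 0.0}
            if not all(np.isfinite(v) for v in comp.values()):
                raise TrainingDiverged(it, comp)
            opt_g.zero_grad()
            total.backward()
            opt_g.step()

            loss_log.append(comp)
            if log_fh and it % cfg.log_interval == 0:
                log_fh.write(json.dumps(comp) + "\n")
                log_fh.flush()
            if it % cfg.eval_interval == 0 or it == cfg.iterations:
                run_eval(it)
                if evals_since_best >= cfg.patience:
                    break
    finally:
        if log_fh:
            log_fh.close()

    if best_params is not None:
        gen.load_arrays(best_params)
    # final evaluation at the selected (minimum validation FID) checkpoint,
    # mirroring the protocol under which the trained model is reported
    checkpoint_metrics = compute_eval(best_iter)
    checkpoint_path = None
    if cfg.checkpoint_dir:
        os.makedirs(cfg.checkpoint_dir, exist_ok=True)
        checkpoint_path = os.path.join(cfg.checkpoint_dir, "generator.npz")
        gen.save(checkpoint_path, extra_meta={"best_iter": best_iter,
                                              "seed": cfg.seed})
        state_model.save(os.path.join(cfg.checkpoint_dir, "state_model.npz"))
    return TrainState(iteration=loss_log[-1]["iteration"] if loss_log else 0,
                      best_fid=best_fid, checkpoint_path=checkpoint_path,
                      log=loss_log, eval_log=eval_log, generator=gen,
                      critic=critic, state_model=state_model,
                      class_denorm=class_denorm, config=cfg, sd_trace=sd_trace,
                      checkpoint_metrics=checkpoint_metrics)
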