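# Methods

`regimediff` synthesizes class-consistent univariate (optionally
multichannel) time series by coupling three ideas: discrete spectral
regimes discovered by clustering, a first-order Markov chain over those
regimes, and a diffusion process whose noise is shaped per regime in the
frequency domain, trained adversarially.

## Model

**Segmentation.** A sequence x ∈ R^{L×C} is cut into N = ⌊(L−l)/h⌋ + 1
overlapping windows of length l at hop h (defaults l = 64, h = 16, i.e.
75% overlap). Trailing samples beyond the last full window are excluded
from training and from the reconstructable range. Windows are z-normalized
(mean 0, variance 1) with the per-window statistics retained so generated
segments can be mapped back to the source scale. Reconstruction is
overlap-add: every position is the arithmetic mean of all windows covering
it. The mean is computed as `ref + mean(deviation from ref)` so that the
unmodified round trip is bit-exact.

**Spectral regimes.** Each window gets a spectral signature: short Hann
frames (length 32, hop 8) are zero-padded to the 256-point analysis FFT
(K = 129 positive-frequency bins), their magnitude spectra averaged, and
log(1+m) applied. Signatures are clustered by k-means into S latent states
(default S = 8, 100 iterations, fixed seed; optional PCA to 32 dimensions,
off by default for small K·C). When labels are available each cluster is
mapped to its majority class (ties to the lowest class id); the map is
stored separately and never alters the state ids. Adjacent-window state
pairs — counted within a source sequence only — give the empirical
transition matrix P̂ with a pseudocount ε = 10⁻³ so no row is zero; a state
never seen as a predecessor gets a uniform row. Per state, the mean member
magnitude spectrum (averaged across channels) is min–max normalized over
bins into a mask M^(s) ∈ [0,1]^K; empty states and constant spectra fall
back to the all-ones (isotropic) mask.

**State-conditioned diffusion.** The forward chain is the
variance-preserving update z_{t+1} = √α_t z_t + √(1−α_t) ε, with a linear
β schedule over T = 50 steps. The noise ε is not white: its expected power
spectrum is proportional to the active state's mask. Because a K-bin mask
must act on a d = 64 latent, noise is synthesized in the time domain —
draw white noise of length 256, scale its one-sided spectrum by √M, invert,
truncate to d. An all-ones mask returns the white noise unchanged, so the
isotropic limit is exact, and the all-zeros mask gives exactly zero. The
state is held fixed across all diffusion steps of a window; the Markov
chain acts only across adjacent windows.

The default β range is [10⁻⁴, 0.1]. With 50 steps this leaves
ᾱ_T ≈ 0.08, i.e. the final latent is genuinely noise-dominated, which is
what generation-from-noise assumes. A shallower range such as β_max = 0.02
leaves ᾱ_T ≈ 0.6 at T = 50 — the final "noised" latent still carries most
of the signal, and latents sampled at generation time are then far from
anything the reverse chain saw during training. The range is exposed in
the configuration.

**Latent semantics.** During training z₀ = Enc(x^(n)) through a learned
linear projection of the flat window — this is what makes the latent
reconstruction penalty ‖z₀ − ẑ₀‖² meaningful. Pure-noise initialization of
the latent applies only at generation time, where z_T is drawn from the
state's mask-shaped distribution.

**Reverse generator.** One reverse step: FFT of the latent (zero-padded to
256 bins), a state-conditioned 1-D convolution across frequency bins
(kernel 5, shared real weights on real and imaginary parts, initialized to
the identity filter), inverse FFT truncated to d, plus a step embedding
(sinusoidal code of t through a two-layer perceptron), then a per-state
FiLM affine γ(s)·ẑ + β(s). The decoder maps ẑ₀ through three temporal
convolutions (kernel 5, dilations 1–2–4) and two per-position linear
projections to an l×C segment. Generation samples the first state from the
target class's empirical state occupancy, evolves states by P̂, denoises
each window with its state, and overlap-adds; segments are rescaled by the
class-average normalization statistics.

The 50-step reverse chain used in training is a single hand-fused
forward/backward computation (numerically identical to composing the
per-step graph, cross-checked in the tests to machine precision); it
provides first-order gradients, which is all the generator objective needs.

**Critic.** A dual-branch critic scores full reconstructed sequences. The
time branch is three strided 1-D convolutions (widths configurable,
default 32-64-64) with LeakyReLU and layer normalization, average-pooled.
The spectral branch averages log(1+|FFT|) magnitudes of non-overlapping
256-sample windows (short sequences zero-padded to one window), making it
invariant to window order and keeping K = 129 across sequence lengths.
Branch features are concatenated and linearly projected to a scalar.

**Objective.** L = L_adv + λ_spec·spectral MSE + λ_KL·KL(P_θ‖P̂) +
λ_rec·MSE(z₀, ẑ₀), with λ_spec = 1.0, λ_KL = 0.1, λ_rec = 1.0. The
spectral term is the mean squared error between full-transform magnitude
spectra of generated and real sequences. P_θ comes from soft-assigning
generated windows to the k-means centroids with softmax(−d²/τ) (τ = 1 by
default) and accumulating expected adjacent-pair counts; both matrices are
ε-smoothed before the KL. The soft assignment makes the term
differentiable; a flag detaches it. Adversarial training is WGAN-GP:
critic loss mean(D(fake)) − mean(D(real)) + 10·mean((‖∇D(x̃)‖−1)²) at
uniform interpolates, three critic steps per generator step, Adam at
lr 10⁻⁴ with betas (0.5, 0.9) for both networks, batch 64, up to 5000
iterations. Validation FID (20% stratified split) is evaluated
periodically; the minimum-FID checkpoint is kept and a patience of 10
evaluations stops training early. After training the model is restored to
the selected checkpoint and re-scored — reported numbers always refer to
that checkpoint, matching how checkpoint selection is defined.

Ablation switches mirror the model's components: `no_mask` (isotropic
noise everywhere), `no_markov` (uniform state sampling, KL weight 0),
`no_diff` (T = 0; the decoder becomes a plain GAN on latent noise, the
reconstruction term vanishes), `no_adv` (no critic).

## Evaluation metrics

All four metrics are computed per seed and reported as mean ± sd
(sample sd, n−1) over the configured seeds (default five).

* **FID** — Fréchet distance between Gaussians fitted to embeddings of
  real and generated sets. The embedding network is a small Elman
  recurrence (hidden 16) trained as a classifier on the real training
  split with a fixed seed and epoch budget, then frozen; its weight hash
  is recorded in the report. The matrix square root is regularized with a
  10⁻⁶ ridge when singular.
* **DTW** — mean dynamic-time-warping cost of each generated sequence to
  its nearest real sequence of the same class (Euclidean local cost, no
  band constraint); random class-matched pairing is available. The dynamic
  program is checked against brute-force enumeration of warping paths.
* **CCA (class consistency accuracy)** — fraction of generated samples
  whose predicted label matches the intended one, scored by a three-layer
  1-D CNN trained on real data only. The classifier must first reach a
  held-out real-data accuracy gate (0.85 by default) or scoring is
  refused. The field also uses "CCA" for canonical correlation analysis;
  here it always means class consistency accuracy.
* **SD (spectral distance)** — per class, the Euclidean distance between
  the mean sum-normalized power spectrum of the generated set and that of
  the real set, averaged over classes weighted by generated counts.
  Comparing set means (rather than each sequence to the class mean) is
  what makes identical sets score exactly zero; the per-sequence variant
  is available behind a flag. Zero-energy sequences use the uniform
  spectrum convention.

## Synthetic benchmark

The fixture generator emulates exactly the structure the model assumes:
class-specific dominant frequency bands, regime switching driven by a
known first-order chain (dwell time one analysis window, so aligned
windows are regime-pure and clustering ground truth is well defined), unit
amplitudes, uniform phases, additive white Gaussian noise (sd 0.3). The
archive-shaped presets are `ecg200-like` (2 classes, length 96, 200
instances, bands 0.03–0.06 and 0.12–0.18 cycles/sample) and
`gunpoint-like` (2 classes, length 150, 200 instances), each with a
stratified half/half train/test split.

What it does not emulate: real morphology (no QRS-like transients),
amplitude modulation, non-stationary noise, class overlap in frequency, or
label noise. Passing tests therefore demonstrate that the machinery
recovers planted spectral/Markov structure and improves spectral fidelity
under adversarial training — not that it matches archive-scale benchmark
scores, which require the real datasets and full-scale multi-seed runs.

## Scaled-down study sizes

The test suite and the acceptance script run the pipeline at sizes chosen
for a single CPU: 200 sequences of length 96, 500 training iterations,
batch 8 sequences (24 windows), critic widths 16-32-32, evaluation every
250 iterations with 16 generated sequences, FID encoder trained 10 epochs.
Regime recovery uses 100 sequences of length 6464 with non-overlapping
windows, giving ≈10⁴ observed window transitions. Training remains at the
full T = 50, S = 8, l = 64, h = 16.

## Numerical choices and edge cases

* Magnitudes inside differentiable paths are √(r²+i²+ε) with ε = 10⁻²⁴
  (the critic's spectral branch subtracts √ε so all-zero input maps to
  exactly zero features).
* k-means clusters emptied during iteration are re-seeded from the points
  farthest from their centers (scikit-learn's relocation rule).
* Constant windows get unit normalization scale instead of dividing by ~0.
* Majority-vote ties, empty states, constant spectra, zero-energy
  sequences: documented deterministic fallbacks (lowest class id, all-ones
  mask, all-ones mask, uniform spectrum).
* Non-finite training losses abort with a diagnostic dump of the last
  component values rather than continuing.
* All randomness flows through explicitly passed seeds or
  `numpy.random.Generator` instances; k-means uses the same seed, so a
  fixed seed reproduces state assignments, loss traces and generated
  samples bitwise.

## Known limitations

* The neural stack runs on the package's own small autodiff engine; it is
  adequate for these model sizes but not for GPU-scale experiments.
* Sequences in one training collection must share a common length (the
  archive convention); variable-length training is out of scope.
* The spectral-mask advantage over isotropic noise is small at the
  smoke-study scale and partially within seed noise; the ablation ordering
  is asserted only as a majority over seeds, not as a margin.
* First-order Markov dynamics only; longer dependencies are represented
  implicitly through window overlap.
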