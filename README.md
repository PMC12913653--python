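# regimediff

Class-preserving time-series synthesis with regime-aware, frequency-shaped
diffusion and adversarial training.

Biomedical and sensor signals (heartbeats, gestures, machine vibration)
tend to move through discrete *spectral regimes* — stretches of time with a
characteristic frequency signature — and generative models that inject
isotropic noise ignore that structure. `regimediff` builds the regime
structure into the generative process itself, so that synthetic sequences
keep both the global spectral shape and the class identity of the data
they imitate. It is aimed at practitioners who need label-faithful
synthetic time series for augmentation, simulation or controlled
evaluation, working from small labeled archives in the UCR tab-separated
convention.

## The model

1. **Windowing.** Each sequence x ∈ R^{L×C} becomes N = ⌊(L−l)/h⌋+1
   overlapping z-normalized windows (l = 64, h = 16 by default).
2. **Regime discovery.** Per-window log-magnitude STFT signatures are
   k-means-clustered into S latent states s_n, aligned to class labels by
   majority vote. Adjacent windows give an empirical Markov transition
   matrix P̂_ij = Pr(s_{n+1}=j | s_n=i), and each state's min–max
   normalized mean spectrum becomes a frequency mask M^(s) ∈ [0,1]^K.
3. **State-conditioned diffusion.** Forward:
   z_{t+1} = √α_t z_t + √(1−α_t) ε_f with ε_f ~ N(0, M^(s_n) ⊙ I) in the
   frequency domain — the noise covariance is diagonal in frequency and
   shaped by the active regime. The reverse generator denoises with a
   state-conditioned spectral filter, a step embedding, and per-state FiLM
   modulation, then decodes each latent to a window; windows are
   overlap-add averaged into the full sequence.
4. **Adversarial training.** A dual-branch critic (temporal Conv1D branch
   + averaged 256-point FFT spectral branch) scores full sequences under
   WGAN-GP. The training objective is

   L = L_adv + λ_spec‖|FFT(x̂)|−|FFT(x)|‖² + λ_KL·KL(P_θ‖P̂) + λ_rec‖z₀−ẑ₀‖²

   with λ_spec = 1.0, λ_KL = 0.1, λ_rec = 1.0; checkpoints are selected by
   minimum validation FID.

Evaluation ships four metrics — FID (Fréchet distance in a learned
recurrent embedding), DTW (nearest class-matched alignment cost), CCA
(class consistency accuracy under a gated real-data classifier) and SD
(distance between normalized power spectra) — each reported as mean ± sd
over seeds. The four ablation variants (NoMask / NoMarkov / NoDiff /
NoAdv) and sensitivity sweeps over S and λ_KL are built in.

A synthetic-fixture module generates class-structured, regime-switching
signals with known ground truth (class frequency bands, true transition
matrix), so the whole pipeline is testable without downloads. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Train on a bundled synthetic 2-class benchmark, generate, evaluate:

```python
import numpy as np
from regimediff import (TrainConfig, fixtures, make_schedule,
                        generate_sequence, train)

train_set, test_set = fixtures.make_ucr_like("ecg200-like", seed=0)
cfg = TrainConfig(iterations=500, batch=8, S=8, eval_interval=250,
                  encoder_epochs=10, critic_channels=(16, 32, 32), seed=0)
state = train(train_set, cfg)
print(f"best validation FID {state.best_fid:.3f} at the selected checkpoint")
print(f"spectral distance: untrained {state.sd_trace[0]:.3f} "
      f"-> checkpoint {state.checkpoint_metrics['sd']:.3f}")

sch = make_schedule(cfg.T, cfg.beta_min, cfg.beta_max)
rng = np.random.default_rng(0)
gs = generate_sequence(1, 3, state.state_model, state.generator, sch,
                       cfg.h, rng, denorm=state.class_denorm[1])
print(f"generated class-1 sequence: shape {gs.values.shape}, "
      f"state path {gs.state_path}")
```

This prints (exact numbers are seed-dependent but reproducible):

```
best validation FID 0.697 at the selected checkpoint
spectral distance: untrained 0.561 -> checkpoint 0.195
generated class-1 sequence: shape (96, 1), state path [6 6 2]
```

The untrained generator's spectra sit far from the real class spectra
(SD ≈ 0.56); after 500 iterations the selected checkpoint has pulled the
class-mean spectrum much closer (SD ≈ 0.20). The generated sequence spans
the covered extent (3 windows of 64 at hop 16 → 96 samples); its first
state is drawn from class 1's empirical state occupancy and subsequent
states follow the learned Markov prior.

The same workflow is available from the shell:

```sh
regimediff prepare  --data train.tsv --out prep/
regimediff train    --data train.tsv --out run/
regimediff generate --model run/ --per-class 10 --out gen.tsv
regimediff evaluate --data test.tsv --generated gen.tsv --out report/
regimediff ablate   --data train.tsv --out ablation/
regimediff sweep    --data train.tsv --out sweep/
```

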