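import numpy as np
import pytest

from regimediff import fixtures, training
from regimediff.embedding import train_classifier, train_encoder
from regimediff.spectral_states import fit_state_model
from regimediff.training import TrainConfig
from regimediff.windowing import segment

SMOKE_SEEDS = [0, 1, 2, 3, 4]


def smoke_config(seed, **overrides):
    """Scaled-down training protocol used for the fixture smoke runs."""
    base = dict(iterations=500, batch=8, S=8, T=50, eval_interval=250,
                encoder_epochs=10, critic_channels=(16, 32, 32), seed=seed)
    base.update(overrides)
    return TrainConfig(**base)


@pytest.fixture(scope="session")
def ecg_fixture():
    """2-class, length-96, 200-sequence synthetic benchmark (train, test)."""
    return fixtures.make_ucr_like("ecg200-like", seed=0)


@pytest.fixture(scope="session")
def gate_classifier(ecg_fixture):
    """CCA gate classifier: fit on the real train split, gated on test."""
    train_set, test_set = ecg_fixture
    x = np.stack([ts.values for ts in train_set])
    y = np.array([ts.label for ts in train_set])
    hx = np.stack([ts.values for ts in test_set])
    hy = np.array([ts.label for ts in test_set])
    return train_classifier(x, y, 2, seed=0, holdout=(hx, hy))


@pytest.fixture(scope="session")
def fid_encoder(ecg_fixture):
    train_set, _ = ecg_fixture
    x = np.stack([ts.values for ts in train_set])
    y = np.array([ts.label for ts in train_set])
    return train_encoder(x, y, 2, seed=0, epochs=20)


@pytest.fixture(scope="session")
def regime_recovery():
    """Two-regime chain with ~1e4 observed window transitions, recovered.

    Returns (spec, state_model, true_window_regimes, flat_states).
    """
    spec = fixtures.two_regime_spec(length=6464, samples=100, noise_sd=0.3,
                                    dwell=64, seed=7)
    series, regime_paths = fixtures.make_dataset(spec)
    wsets = [segment(ts, 64, 64, normalize=True) for ts in series]
    model = fit_state_model(wsets, S=2, seed=0, fft_size=256)
    truth = np.concatenate([
        fixtures.window_regimes(rp, spec.dwell, 64, 64, spec.length)[0]
        for rp in regime_paths])
    states = np.concatenate(model.states)
    return spec, model, truth, states


@pytest.fixture(scope="session")
def smoke_runs(ecg_fixture):
    """The scaled-down training study: 5 seeds full model + 5 seeds NoMask.

    Returns {"full": {seed: TrainState}, "no_mask": {seed: TrainState}}.
    """
    train_set, _ = ecg_fixture
    out = {"full": {}, "no_mask": {}}
    for seed in SMOKE_SEEDS:
        out["full"][seed] = training.train(train_set, smoke_config(seed))
    for seed in SMOKE_SEEDS:
        out["no_mask"][seed] = training.train(train_set,
                                              smoke_config(seed, no_mask=True))
    return out
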