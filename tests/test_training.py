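import numpy as np
import pytest

from regimediff import _engine as E
from regimediff._engine import Tensor
from regimediff.discriminator import Critic
from regimediff.spectral_states import StateModel, fit_state_model, spectral_features
from regimediff.training import (LossWeights, TrainConfig, adversarial_losses,
                                 spectral_loss, train, transition_kl)
from regimediff.windowing import segment

from conftest import smoke_config


class TestSpectralLoss:
    def test_identical_inputs_zero(self):
        x = np.random.default_rng(0).standard_normal((3, 64, 1))
        assert spectral_loss(x, x).item() < 1e-20

    def test_sign_flip_invariant(self):
        x = np.random.default_rng(1).standard_normal((2, 64, 1))
        assert spectral_loss(-x, x).item() < 1e-18

    def test_impulses_at_different_positions_match(self):
        a = np.zeros((1, 32, 1))
        b = np.zeros((1, 32, 1))
        a[0, 3, 0] = 1.0
        b[0, 20, 0] = 1.0     # flat, equal-magnitude spectra
        assert spectral_loss(a, b).item() < 1e-18

    def test_length_mismatch_beyond_overlap_rejected(self):
        with pytest.raises(ValueError):
            spectral_loss(np.zeros((1, 10, 1)), np.zeros((1, 96, 1)))


class TestTransitionKL:
    @pytest.fixture(scope="class")
    def fitted(self, ecg_fixture):
        train_set, _ = ecg_fixture
        wsets = [segment(ts, 64, 16, normalize=True) for ts in train_set[:40]]
        model = fit_state_model(wsets, S=4, seed=0)
        return wsets, model

    def test_real_windows_in_hard_limit_recover_phat(self, fitted):
        """temperature -> 0 reproduces the empirical transitions, so KL ~ 0."""
        wsets, model = fitted
        windows = np.concatenate([ws.windows for ws in wsets])
        kl = transition_kl(windows, model, temperature=1e-4,
                           n_per_seq=wsets[0].n_windows, detach=True)
        assert kl.item() == pytest.approx(0.0, abs=2e-2)

    def test_uniform_vs_identity_hand_value(self):
        """KL of a uniform P_theta against a near-identity target."""
        eps = 1e-6
        S = 2
        model = StateModel(S=S, centroids=np.zeros((S, 3)), states=[],
                           transition=np.eye(S), masks=np.ones((S, 3)),
                           fft_size=4, stft_window=4, stft_hop=4)
        # identical windows => soft assignments are uniform => P_theta uniform
        windows = np.zeros((4, 4, 1))
        kl = transition_kl(windows, model, temperature=1.0, n_per_seq=2,
                           eps=eps, detach=True)
        P_hat = (np.eye(S) + eps)
        P_hat /= P_hat.sum(axis=1, keepdims=True)
        expected = sum(0.5 * np.log(0.5 / P_hat[i, j])
                       for i in range(S) for j in range(S))
        assert kl.item() == pytest.approx(expected, rel=1e-3)

    def test_nonnegative_for_random_inputs(self, fitted):
        wsets, model = fitted
        rng = np.random.default_rng(5)
        windows = rng.standard_normal((12, 64, 1))
        assert transition_kl(windows, model, n_per_seq=3, detach=True).item() >= 0

    def test_gradient_flows_unless_detached(self, fitted):
        wsets, model = fitted
        x = Tensor(np.random.default_rng(6).standard_normal((6, 64, 1)),
                   requires_grad=True)
        kl = transition_kl(x, model, n_per_seq=3)
        kl.backward()
        assert x.grad is not None and np.any(x.grad != 0)
        x2 = Tensor(x.data, requires_grad=True)
        kl2 = transition_kl(x2, model, n_per_seq=3, detach=True)
        assert kl2._parents is None


class TestAdversarialLosses:
    def test_identical_batches_zero_wasserstein_term(self):
        critic = Critic(seed=0)
        x = np.random.default_rng(0).standard_normal((6, 96, 1))
        c_loss, g_loss = adversarial_losses(x, x, critic, gp_coefficient=0.0)
        assert c_loss.item() == pytest.approx(0.0, abs=1e-10)

    def test_unit_norm_linear_critic_has_zero_penalty(self):
        class LinearCritic:
            def __init__(self, w):
                self.w = Tensor(w)

            def __call__(self, x):
                flat = E.reshape(x, (x.shape[0], -1))
                return E.matmul(flat, self.w)

        w = np.random.default_rng(1).standard_normal((96, 1))
        w /= np.linalg.norm(w)
        critic = LinearCritic(w)
        x = np.random.default_rng(2).standard_normal((4, 96, 1))
        y = np.random.default_rng(3).standard_normal((4, 96, 1))
        c_with, _ = adversarial_losses(x, y, critic, gp_coefficient=10.0,
                                       rng=np.random.default_rng(0))
        c_without, _ = adversarial_losses(x, y, critic, gp_coefficient=0.0,
                                          rng=np.random.default_rng(0))
        assert c_with.item() == pytest.approx(c_without.item(), abs=1e-8)

    def test_penalty_nonnegative(self):
        critic = Critic(seed=4)
        x = np.random.default_rng(4).standard_normal((4, 96, 1))
        y = np.random.default_rng(5).standard_normal((4, 96, 1))
        c_with, _ = adversarial_losses(x, y, critic, gp_coefficient=10.0,
                                       rng=np.random.default_rng(1))
        c_without, _ = adversarial_losses(x, y, critic, gp_coefficient=0.0,
                                          rng=np.random.default_rng(1))
        assert c_with.item() >= c_without.item() - 1e-12

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_spec=-1.0)


class TestTrainLoop:
    def test_short_run_completes_with_finite_losses_and_checkpoint(
            self, ecg_fixture, tmp_path):
        train_set, _ = ecg_fixture
        cfg = smoke_config(0, iterations=30, eval_interval=15, batch=6, S=4,
                           encoder_epochs=2, checkpoint_dir=str(tmp_path),
                           log_dir=str(tmp_path))
        state = train(train_set[:40], cfg)
        assert all(np.isfinite(row["total"]) for row in state.log)
        assert (tmp_path / "generator.npz").exists()
        assert (tmp_path / "state_model.npz").exists()
        assert (tmp_path / "config.json").exists()
        assert (tmp_path / "train_log.jsonl").exists()

    def test_total_loss_is_sum_of_logged_components(self, ecg_fixture):
        train_set, _ = ecg_fixture
        cfg = smoke_config(1, iterations=8, eval_interval=100, batch=4, S=4,
                           encoder_epochs=1)
        state = train(train_set[:24], cfg)
        w = cfg.weights
        for row in state.log:
            recon = (row["adv"] + w.lambda_spec * row["spec"] +
                     w.lambda_kl * row["kl"] + w.lambda_rec * row["rec"])
            assert row["total"] == pytest.approx(recon, rel=1e-12)

    def test_same_seed_reproduces_loss_trace(self, ecg_fixture):
        train_set, _ = ecg_fixture
        cfg = smoke_config(2, iterations=6, eval_interval=100, batch=4, S=4,
                           encoder_epochs=1)
        a = train(train_set[:24], cfg)
        b = train(train_set[:24], smoke_config(2, iterations=6, eval_interval=100,
                                               batch=4, S=4, encoder_epochs=1))
        assert [r["total"] for r in a.log] == [r["total"] for r in b.log]

    def test_zero_weights_reduce_to_pure_wgan_gp(self, ecg_fixture):
        train_set, _ = ecg_fixture
        cfg = smoke_config(3, iterations=5, eval_interval=100, batch=4, S=4,
                           encoder_epochs=1)
        cfg.weights = LossWeights(lambda_spec=0.0, lambda_kl=0.0, lambda_rec=0.0)
        state = train(train_set[:24], cfg)
        for row in state.log:
            assert row["total"] == pytest.approx(row["adv"], rel=1e-12)

    @pytest.mark.parametrize("flag", ["no_mask", "no_markov", "no_diff", "no_adv"])
    def test_ablation_variants_run(self, ecg_fixture, flag):
        train_set, _ = ecg_fixture
        cfg = smoke_config(4, iterations=5, eval_interval=100, batch=4, S=4,
                           encoder_epochs=1, **{flag: True})
        state = train(train_set[:24], cfg)
        assert all(np.isfinite(row["total"]) for row in state.log)
        if flag == "no_adv":
            assert all(row["adv"] == 0.0 for row in state.log)
        if flag == "no_markov":
            assert all(row["kl"] == 0.0 for row in state.log)
        if flag == "no_diff":
            assert all(row["rec"] == 0.0 for row in state.log)

    def test_no_adv_training_reduces_spectral_loss(self, ecg_fixture):
        train_set, _ = ecg_fixture
        cfg = smoke_config(5, iterations=120, eval_interval=1000, batch=8, S=4,
                           encoder_epochs=1, no_adv=True)
        state = train(train_set[:40], cfg)
        first = np.mean([r["spec"] for r in state.log[:10]])
        last = np.mean([r["spec"] for r in state.log[-10:]])
        assert last < first


class TestSmokeStudy:
    """The scaled-down multi-seed study on the 2-class fixture."""

    def test_all_runs_complete_with_finite_losses(self, smoke_runs):
        for group in smoke_runs.values():
            for state in group.values():
                assert all(np.isfinite(r["total"]) for r in state.log)
                assert state.iteration == 500

    def test_spectral_distance_decreases_in_most_seeds(self, smoke_runs):
        traces = [s.sd_trace for s in smoke_runs["full"].values()]
        decreased = sum(1 for tr in traces if tr[-1] < tr[0])
        assert decreased >= 4

    def test_full_model_beats_no_mask_on_sd_in_majority_of_seeds(self, smoke_runs):
        wins = sum(
            1 for seed in smoke_runs["full"]
            if smoke_runs["full"][seed].sd_trace[-1]
            <= smoke_runs["no_mask"][seed].sd_trace[-1])
        assert wins >= 3
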