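import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from regimediff.spectral_states import (StateModel, assign_states, build_masks,
                                        estimate_transitions, spectral_features)


def sinusoid_windows(k0, n=8, l=64, fft_size=256, seed=0):
    """Windows holding a pure tone at bin k0 of the fft_size grid."""
    rng = np.random.default_rng(seed)
    t = np.arange(l)
    return np.stack([np.sin(2 * np.pi * k0 / fft_size * t + rng.uniform(0, 2 * np.pi))
                     for _ in range(n)])[:, :, None]


def best_match_agreement(a, b):
    """Permutation-invariant label agreement via optimal assignment."""
    a, b = np.asarray(a), np.asarray(b)
    k = max(a.max(), b.max()) + 1
    conf = np.zeros((k, k))
    for x, y in zip(a, b):
        conf[x, y] += 1
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(a)


class TestSpectralFeatures:
    def test_zero_window_gives_zero_features(self):
        feats = spectral_features(np.zeros((3, 64, 1)))
        assert np.all(feats.features == 0)

    def test_bin_count_is_half_fft_plus_one(self):
        feats = spectral_features(np.random.default_rng(0).standard_normal((2, 64, 1)),
                                  fft_size=256)
        assert feats.n_bins == 129
        assert feats.features.shape == (2, 129)

    @pytest.mark.parametrize("k0", [20, 32, 48])
    def test_tone_peaks_at_its_bin(self, k0):
        feats = spectral_features(sinusoid_windows(k0))
        assert np.all(np.argmax(feats.features, axis=1) == k0)

    def test_multichannel_concatenates(self):
        w = np.random.default_rng(1).standard_normal((4, 64, 3))
        feats = spectral_features(w, fft_size=128)
        assert feats.features.shape == (4, 65 * 3)

    def test_non_power_of_two_warns(self):
        with pytest.warns(UserWarning, match="power of two"):
            spectral_features(np.ones((2, 10, 1)), fft_size=100)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            spectral_features(np.empty((0, 64, 1)))


class TestAssignStates:
    def test_separated_groups_recovered_exactly(self):
        w = np.concatenate([sinusoid_windows(16, n=10, seed=1),
                            sinusoid_windows(80, n=10, seed=2)])
        feats = spectral_features(w)
        states, _, _, _, _ = assign_states(feats, S=2, seed=0)
        truth = np.array([0] * 10 + [1] * 10)
        assert best_match_agreement(states, truth) == 1.0

    def test_deterministic_given_seed(self):
        w = np.random.default_rng(3).standard_normal((30, 64, 1))
        feats = spectral_features(w)
        s1, c1, _, _, _ = assign_states(feats, S=4, seed=9)
        s2, c2, _, _, _ = assign_states(feats, S=4, seed=9)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(c1, c2)

    def test_identical_windows_collapse_to_one_state(self):
        w = np.tile(np.sin(np.arange(64) / 3)[None, :, None], (10, 1, 1))
        feats = spectral_features(w)
        states, _, _, _, _ = assign_states(feats, S=2, seed=0)
        assert len(np.unique(states)) == 1

    def test_majority_vote_maps_clusters_to_classes(self):
        w = np.concatenate([sinusoid_windows(16, n=10, seed=1),
                            sinusoid_windows(80, n=10, seed=2)])
        labels = np.array([1] * 10 + [0] * 10)
        feats = spectral_features(w)
        states, _, c2c, _, _ = assign_states(feats, S=2, seed=0, labels=labels)
        for s in range(2):
            member_labels = labels[states == s]
            assert c2c[s] == np.bincount(member_labels).argmax()

    def test_too_few_states_rejected(self):
        feats = spectral_features(np.ones((5, 64, 1)))
        with pytest.raises(ValueError):
            assign_states(feats, S=1, seed=0)


class TestEstimateTransitions:
    def test_hand_counted_path(self):
        # pairs: 0->0, 0->1, 1->1, 1->0  => both rows [1/2, 1/2]
        P = estimate_transitions([np.array([0, 0, 1, 1, 0])], S=2, smoothing=0.0)
        np.testing.assert_allclose(P, [[0.5, 0.5], [0.5, 0.5]])

    def test_deterministic_cycle(self):
        P = estimate_transitions([np.array([0, 1, 0, 1])], S=2, smoothing=0.0)
        np.testing.assert_allclose(P, [[0, 1], [1, 0]])

    def test_no_cross_sequence_transitions(self):
        # two sequences; the 1->0 jump across the boundary must not count
        P = estimate_transitions([np.array([0, 1]), np.array([0, 1])], S=2,
                                 smoothing=0.0)
        np.testing.assert_allclose(P[0], [0, 1])

    def test_monte_carlo_consistency(self):
        P_true = np.array([[0.85, 0.15], [0.3, 0.7]])
        rng = np.random.default_rng(0)
        path = [0]
        for _ in range(10 ** 4):
            path.append(rng.choice(2, p=P_true[path[-1]]))
        P = estimate_transitions([np.array(path)], S=2, smoothing=0.0)
        assert np.abs(P - P_true).max() <= 0.05

    def test_rows_stochastic_with_smoothing(self):
        rng = np.random.default_rng(1)
        P = estimate_transitions([rng.integers(0, 3, 50)], S=5, smoothing=1e-3)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(P >= 0)
        # states 3, 4 never occur as predecessors with counts only from data
        P0 = estimate_transitions([np.array([0, 1, 0])], S=3, smoothing=0.0)
        np.testing.assert_allclose(P0[2], [1 / 3] * 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_transitions([np.array([0])], S=2)


class TestBuildMasks:
    def test_bounds_and_extremes(self):
        rng = np.random.default_rng(2)
        mags = rng.uniform(0.1, 5.0, (20, 65, 1))
        states = rng.integers(0, 3, 20)
        masks = build_masks(mags, states, S=3)
        assert np.all(masks >= 0) and np.all(masks <= 1)
        for s in range(3):
            if (states == s).any():
                assert masks[s].min() == 0.0 and masks[s].max() == 1.0

    def test_single_member_state_is_normalized_spectrum(self):
        mags = np.random.default_rng(3).uniform(1, 2, (1, 65, 1))
        masks = build_masks(mags, np.array([0]), S=1)
        m = mags[0, :, 0]
        np.testing.assert_allclose(masks[0], (m - m.min()) / (m.max() - m.min()))

    def test_tone_state_mask_peaks_at_bin(self):
        feats = spectral_features(sinusoid_windows(40, n=6))
        masks = build_masks(feats.magnitudes, np.zeros(6, dtype=int), S=1)
        assert np.argmax(masks[0]) == 40
        assert masks[0][40] == 1.0

    def test_empty_state_isotropic_fallback(self):
        masks = build_masks(np.ones((4, 65, 1)) * [[1]], np.zeros(4, dtype=int), S=2)
        np.testing.assert_array_equal(masks[1], 1.0)

    def test_constant_spectrum_isotropic_fallback(self):
        masks = build_masks(np.full((3, 65, 1), 2.0), np.zeros(3, dtype=int), S=1)
        np.testing.assert_array_equal(masks[0], 1.0)


class TestRegimeRecovery:
    def test_cluster_agreement_and_transition_recovery(self, regime_recovery):
        spec, model, truth, states = regime_recovery
        n_transitions = sum(len(s) - 1 for s in model.states)
        assert n_transitions >= 10 ** 4 - len(model.states)
        assert best_match_agreement(states, truth) >= 0.9
        # align estimated states to true regimes before comparing matrices
        conf = np.zeros((2, 2))
        for a, b in zip(states, truth):
            conf[a, b] += 1
        perm = conf.argmax(axis=1)
        P_aligned = model.transition[np.argsort(perm)][:, np.argsort(perm)]
        assert np.abs(P_aligned - spec.transitions[0]).max() <= 0.05

    def test_rows_sum_to_one(self, regime_recovery):
        _, model, _, _ = regime_recovery
        np.testing.assert_allclose(model.transition.sum(axis=1), 1.0, atol=1e-9)

    def test_masks_reflect_disjoint_bands(self, regime_recovery):
        spec, model, truth, states = regime_recovery
        # each state's mask peak must fall inside one of the two true bands
        bands_bins = [(lo * 256, hi * 256) for lo, hi in spec.class_bands[0]]
        peaks = sorted(np.argmax(model.masks, axis=1))
        for peak, (lo, hi) in zip(peaks, bands_bins):
            assert lo - 4 <= peak <= hi + 4


def test_state_model_round_trips_through_archive(tmp_path, regime_recovery):
    _, model, _, _ = regime_recovery
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = StateModel.load(path)
    np.testing.assert_array_equal(loaded.masks, model.masks)
    np.testing.assert_array_equal(loaded.transition, model.transition)
    np.testing.assert_array_equal(loaded.centroids, model.centroids)
    assert loaded.S == model.S
    assert len(loaded.states) == len(model.states)
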