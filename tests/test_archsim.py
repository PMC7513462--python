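"""Linear dynamical-system hierarchies: construction, closed form, delays."""

import numpy as np
import pytest

from megcascade.archsim import (
    build_architecture,
    delay_experiment,
    predicted_decoding,
    predicted_tg,
    simulate,
)
from megcascade.tg import generalization_durations


def matrix_power_oracle(A, B, input_steps, n_steps):
    """Closed form X_t = sum_s A^(t-1-s) B u_s, evaluated independently."""
    n = A.shape[0]
    X = np.zeros((n, n_steps + 1))
    for t in range(1, n_steps + 1):
        acc = np.zeros(n)
        for s in input_steps:
            if s <= t - 1:
                acc += np.linalg.matrix_power(A, t - 1 - s) @ B[:, 0]
        X[:, t] = acc
    return X


class TestBuild:
    def test_maintain_diagonal_is_identity_on_own_features(self):
        arch = build_architecture("maintain", n_layers=5)
        for l in range(1, 6):
            units = arch.units_of(layer=l, feature=l)
            assert np.all(np.diag(arch.A)[units] == 1.0)
        off_units = arch.units_of(layer=2, feature=1)
        assert np.all(np.diag(arch.A)[off_units] == 0.0)

    def test_broadcast_is_strictly_feedforward(self):
        arch = build_architecture("broadcast", n_layers=4)
        rows, cols = np.nonzero(arch.A)
        assert np.all(arch.layer_of[rows] > arch.layer_of[cols])

    def test_hybrid_matches_hand_built_two_layer_matrix(self):
        arch = build_architecture("hybrid", n_layers=2, weights=(1.0, 1.0, 1.0))
        # hand-built: units (layer, feature, phase) in construction order
        # L1: (1,1,0),(1,1,1),(1,2,0),(1,2,1); L2: (2,1,0),(2,1,1),(2,2,0),(2,2,1)
        expected = np.zeros((8, 8))
        expected[4, 0] = 1.0  # propagate feature 1 forward
        expected[6, 0] = 1.0  # generation: (1,1) -> (2,2)
        for a in (0, 6):  # rotations in own-feature slots (1,1) and (2,2)
            expected[a, a + 1] = -1.0
            expected[a + 1, a] = 1.0
        np.testing.assert_array_equal(arch.A, expected)
        assert arch.B[0, 0] == 1.0 and arch.B.sum() == 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_architecture("feedback", 5)

    def test_explosive_weights_warn(self):
        with pytest.warns(RuntimeWarning, match="spectral radius"):
            build_architecture("maintain", 3, weights=(1.5, 1.0, 1.0))


class TestSimulate:
    def test_zero_connectivity_single_transient(self):
        arch = build_architecture("maintain", 3, weights=(0.0, 0.0, 0.0))
        sim = simulate(arch, input_steps=(1,), n_steps=6)
        l1 = arch.units_of(layer=1, feature=1)[0]
        assert sim.activations[l1, 2] == 1.0
        assert np.abs(sim.activations).sum() == 1.0  # nothing else, ever

    def test_feedforward_chain_matches_matrix_power_oracle(self):
        arch = build_architecture("broadcast", 5, weights=(0.0, 1.0, 0.0))
        sim = simulate(arch, input_steps=(1,), n_steps=8)
        oracle = matrix_power_oracle(arch.A, arch.B, (1,), 8)
        np.testing.assert_allclose(sim.activations, oracle, atol=1e-12)
        # generated feature k ignites layer k exactly at step k+1
        for k in range(1, 6):
            unit = arch.units_of(layer=k, feature=k)[0]
            first = np.flatnonzero(np.abs(sim.activations[unit]) > 1e-12)
            assert first[0] == k + 1

    def test_pure_maintenance_holds_activation(self):
        arch = build_architecture("maintain", 3, weights=(1.0, 0.0, 0.0))
        # no feedforward: only layer 1 ever activates, and it persists
        sim = simulate(arch, input_steps=(1,), n_steps=10)
        l1 = arch.units_of(layer=1, feature=1)[0]
        assert np.all(sim.activations[l1, 2:] == 1.0)

    def test_superposition_is_exact(self):
        arch = build_architecture("hybrid", 4)
        a = simulate(arch, input_steps=(1,), n_steps=12).activations
        b = simulate(arch, input_steps=(4,), n_steps=12).activations
        both = simulate(arch, input_steps=(1, 4), n_steps=12).activations
        np.testing.assert_allclose(both, a + b, atol=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_random_small_systems_match_closed_form(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 10))
        A = rng.standard_normal((n, n)) * 0.4
        B = np.zeros((n, 1))
        B[0, 0] = 1.0
        from megcascade.archsim import Architecture

        arch = Architecture(A=A, B=B, layer_of=np.ones(n, int),
                            feature_of=np.ones(n, int), kind="maintain")
        steps = sorted(rng.choice(range(8), 2, replace=False))
        sim = simulate(arch, input_steps=steps, n_steps=15)
        oracle = matrix_power_oracle(A, B, steps, 15)
        np.testing.assert_allclose(sim.activations, oracle, atol=1e-12)


class TestPredictedDecoding:
    def test_maintain_keeps_each_feature_in_its_layer(self):
        arch = build_architecture("maintain", 4)
        sim = simulate(arch, input_steps=(1,), n_steps=8)
        pred = predicted_decoding(sim)
        for f in range(1, 5):
            dec = pred["decodable"][f - 1, f - 1]  # own layer
            first = np.flatnonzero(dec)
            assert first.size and np.all(dec[first[0]:])

    def test_broadcast_propagates_low_level_features_upward(self):
        # no skip connections: the wave climbs strictly one layer per step
        arch = build_architecture("broadcast", 4, weights=(0.0, 1.0, 0.0))
        sim = simulate(arch, input_steps=(1,), n_steps=8)
        pred = predicted_decoding(sim)
        onsets = []
        for l in range(1, 5):  # feature 1 appears later in higher layers
            dec = pred["decodable"][0, l - 1]
            onsets.append(np.flatnonzero(dec)[0])
        assert onsets == sorted(onsets) and len(set(onsets)) == 4

    def test_zero_architecture_decays_to_nothing(self):
        arch = build_architecture("maintain", 3, weights=(0.0, 0.0, 0.0))
        sim = simulate(arch, input_steps=(1,), n_steps=8)
        pred = predicted_decoding(sim)
        assert not pred["decodable"][:, :, 4:].any()


class TestDelay:
    def test_downstream_layers_shift_by_exact_delay(self):
        # skip-free chain: skips would feed the top layer ahead of the delay
        arch = build_architecture("broadcast", 5, weights=(0.0, 1.0, 0.0))
        plain = simulate(arch, input_steps=(1,), n_steps=120).activations
        # layer 3 ignites at t=4; freezing from t=4 withholds its output
        delay = delay_experiment(arch, layer=3, delay_steps=100, insert_at=4,
                                 n_steps=120).activations
        up = np.concatenate([arch.units_of(layer=1), arch.units_of(layer=2)])
        np.testing.assert_allclose(delay[up], plain[up], atol=1e-12)
        for l in (4, 5):
            units = arch.units_of(layer=l)
            np.testing.assert_allclose(
                delay[units, 100 + l + 1], plain[units, l + 1], atol=1e-12)
            assert np.abs(delay[units, : 100 + l + 1]).max() == 0.0

    def test_zero_delay_identical_to_plain(self):
        arch = build_architecture("hybrid", 4)
        plain = simulate(arch, input_steps=(1,), n_steps=20).activations
        delay = delay_experiment(arch, layer=2, delay_steps=0, insert_at=4,
                                 n_steps=20).activations
        np.testing.assert_array_equal(plain, delay)

    def test_two_delays_compose_additively(self):
        arch = build_architecture("broadcast", 5, weights=(0.0, 1.0, 0.0))
        single = delay_experiment(arch, layer=2, delay_steps=10, insert_at=3,
                                  n_steps=60).activations
        # after the first delay, layer 3 ignites at t=14; freeze it right then
        double = delay_experiment(arch, layer=(2, 3), delay_steps=(10, 7),
                                  insert_at=(3, 14), n_steps=60).activations
        plain = simulate(arch, input_steps=(1,), n_steps=60).activations
        l5 = arch.units_of(layer=5)
        t0 = 6  # layer-5 ignition in the plain run
        assert np.abs(plain[l5, t0]).max() > 0
        np.testing.assert_allclose(single[l5, t0 + 10], plain[l5, t0],
                                   atol=1e-12)
        np.testing.assert_allclose(double[l5, t0 + 17], plain[l5, t0],
                                   atol=1e-12)

    def test_overflowing_delay_rejected(self):
        arch = build_architecture("maintain", 3)
        with pytest.raises(ValueError, match="past the end"):
            delay_experiment(arch, layer=2, delay_steps=10, insert_at=5,
                             n_steps=8)


class TestPredictedTG:
    def test_maintain_square_dynamic_diagonal(self):
        ratios = {}
        for kind in ("maintain", "dynamic"):
            arch = build_architecture(kind, n_layers=5)
            tg, _ = predicted_tg(arch, n_trials=60, noise_sd=0.4, seed=2,
                                 feature=1, n_steps=8)
            dur = generalization_durations(tg, tg.scores >= 0.8)
            ratios[kind] = dur["ratio"]
        assert ratios["maintain"] > 0.9
        assert ratios["dynamic"] < 0.5

    def test_overwhelming_noise_scores_at_chance(self):
        arch = build_architecture("maintain", 4)
        tg, _ = predicted_tg(arch, n_trials=40, noise_sd=500.0, seed=3,
                             feature=1, n_steps=8)
        assert abs(np.nanmean(tg.scores) - 0.5) < 0.1

    def test_too_few_trials_rejected(self):
        arch = build_architecture("maintain", 3)
        with pytest.raises(ValueError):
            predicted_tg(arch, n_trials=10)
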