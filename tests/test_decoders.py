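"""AUC scoring, temporal/spatial decoding, peak metrics, leakage guards."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from megcascade.decoders import (
    ScoreSeries,
    fit_fold_models,
    normalize_by_peak,
    peak_and_onset,
    score_auc,
    spatial_decode,
    temporal_decode,
)
from megcascade.pipeline import active_epochs, active_target
from megcascade.synthetic import (
    EpochSet,
    default_encoding_specs,
    simulate_epochs,
    simulate_source_geometry,
)


def brute_force_auc(dv, labels):
    """O(n^2) pairwise-count oracle: P(score+ > score-) + 0.5 P(tie)."""
    pos = dv[labels > 0]
    neg = dv[labels < 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestScoreAUC:
    def test_perfect_separation(self):
        assert score_auc([1, 2, 3, 10, 11], [-1, -1, -1, 1, 1]) == 1.0

    def test_label_flip_symmetry(self, rng):
        dv = rng.standard_normal(40)
        y = np.sign(rng.standard_normal(40))
        y[y == 0] = 1
        assert score_auc(dv, y) == pytest.approx(1 - score_auc(dv, -y))

    def test_hand_worked_example(self):
        # decision values (0.1, 0.4, 0.35, 0.8) for labels (-,-,+,+):
        # pairs won 3 of 4 -> 0.75
        assert score_auc([0.1, 0.4, 0.35, 0.8], [-1, -1, 1, 1]) == 0.75

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pairwise_oracle_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        dv = rng.integers(0, 6, 50).astype(float)  # many ties
        y = np.where(rng.random(50) < 0.4, 1.0, -1.0)
        if len(set(y)) < 2:
            y[0] = -y[0]
        expected = brute_force_auc(dv, y)
        assert score_auc(dv, y) == expected
        assert roc_auc_score((y > 0).astype(int), dv) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            score_auc([0.1, 0.2], [1, 1])


class TestTemporalDecode:
    def test_null_target_scores_at_chance(self, small_active, rng):
        epochs, table = small_active
        y = np.where(rng.random(epochs.n_trials) < 0.5, 1.0, -1.0)
        series = temporal_decode(epochs, y, "classify", 5, 0)
        assert abs(series.scores.mean() - 0.5) < 0.05
        assert series.chance == 0.5 and series.metric == "AUC"

    def test_planted_window_recovered(self, small_table):
        specs = {f: replace(s, amplitude=(3.0 if f == "position" else 0.0))
                 for f, s in default_encoding_specs().items()}
        ep = simulate_epochs(small_table, specs, 10, 0.3, "sensor", 1,
                             50.0, -100.0, 700.0)
        epa = active_epochs(ep, small_table)
        series = temporal_decode(epa, active_target(small_table, "position"),
                                 "classify", 5, 0)
        sp = default_encoding_specs()["position"]
        inside = (series.axis > sp.onset_ms + 40) & (series.axis < 400)
        outside = series.axis < sp.onset_ms - 40
        assert series.scores[inside].min() > 0.9
        assert abs(series.scores[outside].mean() - 0.5) < 0.1

    def test_regression_path_scores_uncertainty(self, small_active):
        epochs, table = small_active
        series = temporal_decode(epochs, active_target(table, "uncertainty"),
                                 "regress", 5, 0)
        assert series.metric == "spearman_r" and series.chance == 0.0
        assert series.scores.max() > 0.2

    def test_zero_variance_channel_warns(self, small_active):
        epochs, table = small_active
        data = epochs.data.copy()
        data[:, 0, :] = 3.14
        flat = EpochSet(data, epochs.times_ms)
        y = active_target(table, "position")
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            temporal_decode(flat, y, "classify", 5, 0)

    def test_nonbinary_classification_target_rejected(self, small_active):
        epochs, table = small_active
        with pytest.raises(ValueError, match="binary"):
            temporal_decode(epochs, np.arange(epochs.n_trials, dtype=float),
                            "classify", 5, 0)


class TestSpatialDecode:
    def test_spatial_peak_order_follows_planted_centers(self, small_table):
        coords = simulate_source_geometry(80, seed=9)
        base = default_encoding_specs()
        specs = {f: replace(s, amplitude=0.0) for f, s in base.items()}
        specs["position"] = replace(base["position"], amplitude=2.0,
                                    pattern_center_y=-0.7)
        specs["category"] = replace(base["category"], amplitude=2.0,
                                    pattern_center_y=0.7)
        ep = simulate_epochs(small_table, specs, 80, 0.5, "source", 2,
                             50.0, -100.0, 700.0, coords=coords)
        epa = active_epochs(ep, small_table)
        peaks = {}
        for feat in ("position", "category"):
            series = spatial_decode(epa, active_target(small_table, feat),
                                    "classify", (0.0, 700.0), 5, 0)
            peaks[feat] = coords[np.argmax(series.scores), 1]
        assert peaks["position"] < peaks["category"]

    def test_all_noise_scores_at_chance(self, small_table, rng):
        data = rng.standard_normal((len(small_table), 8, 31))
        ep = EpochSet(data, np.linspace(0, 600, 31))
        epa = active_epochs(ep, small_table)
        series = spatial_decode(epa, active_target(small_table, "position"),
                                "classify", (0.0, 600.0), 5, 0)
        assert abs(series.scores.mean() - 0.5) < 0.06

    def test_window_outside_epoch_rejected(self, small_active):
        epochs, table = small_active
        with pytest.raises(ValueError, match="window"):
            spatial_decode(epochs, active_target(table, "position"),
                           "classify", (-500.0, 700.0), 5, 0)


class TestPeakAndNormalize:
    def test_onset_and_interpolated_peak(self):
        t = np.arange(0, 200, 10.0)
        scores = 0.5 + 0.4 * np.exp(-0.5 * ((t - 97) / 30) ** 2)
        series = ScoreSeries(scores, t, "AUC", 0.5, 5)
        mask = scores > 0.55
        onset, peak = peak_and_onset(series, mask, interpolate=True)
        assert onset == t[np.argmax(mask)]
        assert peak == pytest.approx(97, abs=2)

    def test_empty_mask_gives_missing_onset(self):
        series = ScoreSeries(np.full(10, 0.5), np.arange(10.0), "AUC", 0.5, 5)
        onset, peak = peak_and_onset(series, np.zeros(10, bool))
        assert onset is None
        assert np.isfinite(peak)

    def test_normalize_by_peak_scales_to_one(self):
        t = np.arange(10.0)
        a = ScoreSeries(0.5 + 0.3 * np.sin(t / 3) ** 2, t, "AUC", 0.5, 5)
        b = ScoreSeries(0.5 + 0.1 * np.sin(t / 3) ** 2, t, "AUC", 0.5, 5)
        na, nb = normalize_by_peak([a, b])
        assert na.scores.max() == 1.0
        np.testing.assert_allclose(na.scores, nb.scores, atol=1e-12)

    def test_chance_level_curve_rejected(self):
        flat = ScoreSeries(np.full(10, 0.5), np.arange(10.0), "AUC", 0.5, 5)
        with pytest.raises(ValueError, match="chance"):
            normalize_by_peak([flat])


class TestLeakageGuard:
    def test_heldout_corruption_changes_nothing_fitted(self, small_active):
        epochs, table = small_active
        y = active_target(table, "position")
        folds, W, B, MU, SD = fit_fold_models(epochs, y, "classify", 5, 0)
        corrupted = EpochSet(epochs.data.copy(), epochs.times_ms)
        # scramble every held-out trial of fold 0 wildly
        _, te = folds[0]
        corrupted.data[te] = 1e3
        folds2, W2, B2, MU2, SD2 = fit_fold_models(
            corrupted, y, "classify", 5, 0,
            train_idx_list=[tr for tr, _ in [folds[0]]])
        k = 0
        assert np.array_equal(W[k], W2[0])
        assert np.array_equal(B[k], B2[0])
        assert np.array_equal(MU[k], MU2[0])
        assert np.array_equal(SD[k], SD2[0])
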