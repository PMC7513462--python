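"""Synthetic epoch/behavior generator: structure, invariants, error paths."""

from dataclasses import replace

import numpy as np
import pytest

from megcascade.design import generate_design
from megcascade.synthetic import (
    EncodingSpec,
    EpochSet,
    default_encoding_specs,
    simulate_behavior,
    simulate_disk_reports,
    simulate_epochs,
    simulate_source_geometry,
)


@pytest.fixture(scope="module")
def dispersed_rt_table():
    """Behavior with wide, ambiguity-independent RT dispersion."""
    table = generate_design(4, 36, 4, seed=71)
    return simulate_behavior(table, seed=72, uncertainty_weight=0.0,
                             noise_sd=0.6)


def silenced(except_for=None, **overrides):
    """Default specs with all amplitudes zeroed except one (optionally
    overridden)."""
    specs = {}
    for f, s in default_encoding_specs().items():
        if f == except_for:
            specs[f] = replace(s, **overrides) if overrides else s
        else:
            specs[f] = replace(s, amplitude=0.0)
    return specs


class TestBehavior:
    def test_steep_slope_perfect_on_endpoints(self):
        table = generate_design(2, 36, 4, seed=0)
        table = simulate_behavior(table, psychometric_slope=1e3, seed=1)
        endpoints = table[table.active & table.evidence_step.isin([1, 8])]
        assert (endpoints.correct == 1.0).all()

    def test_ambiguous_worse_than_endpoints(self):
        table = generate_design(10, 40, 8, seed=0)
        table = simulate_behavior(table, psychometric_slope=8.0, seed=1)
        act = table[table.active]
        stim_cat = np.where(act.letter_evidence > 0.5, 1.0, -1.0)
        match = (act.report == stim_cat).astype(float)
        amb = act.evidence_step.isin([4, 5])
        assert match[~amb].mean() > match[amb].mean() + 0.1

    def test_zero_stage_delays_give_exact_base_rt(self):
        table = generate_design(2, 36, 4, seed=0)
        table = simulate_behavior(
            table, rt_base_ms=500.0,
            stage_delays={f: 0.0 for f in default_encoding_specs()}, seed=1)
        assert (table[table.active].rt_ms == 500.0).all()

    def test_rt_increases_with_uncertainty(self):
        table = generate_design(10, 40, 8, seed=0)
        table = simulate_behavior(table, seed=1)
        act = table[table.active]
        lo = act[act.uncertainty == 0].rt_ms.mean()
        hi = act[act.uncertainty == act.uncertainty.max()].rt_ms.mean()
        assert hi > lo + 20

    def test_nonpositive_base_rt_rejected(self):
        table = generate_design(2, 36, 4, seed=0)
        with pytest.raises(ValueError):
            simulate_behavior(table, rt_base_ms=0.0)

    def test_motor_code_follows_mapping_identity_report(self):
        table = generate_design(2, 36, 4, seed=0)
        table = simulate_behavior(table, seed=1)
        act = table[table.active]
        expected = act.mapping * act.identity_code * act.category_code
        assert np.array_equal(act.motor_code.to_numpy(), expected.to_numpy())


class TestEpochs:
    def test_noise_free_stable_code_is_rank_one(self, small_table):
        specs = silenced("position", stability=1.0)
        ep = simulate_epochs(small_table, specs, 8, 0.0, "sensor", 0,
                             50.0, -100.0, 700.0)
        sp = specs["position"]
        window = (ep.times_ms > sp.onset_ms) & (ep.times_ms < sp.offset_ms)
        flat = ep.data[:, :, window].transpose(1, 0, 2).reshape(8, -1)
        s = np.linalg.svd(flat, compute_uv=False)
        assert s[1] < 1e-10 * s[0]

    def test_zero_amplitude_gives_pure_noise_stats(self, small_table):
        specs = {f: replace(s, amplitude=0.0)
                 for f, s in default_encoding_specs().items()}
        ep = simulate_epochs(small_table, specs, 8, 1.0, "sensor", 0,
                             50.0, -100.0, 700.0)
        assert abs(ep.data.mean()) < 0.01
        assert ep.data.std() == pytest.approx(1.0, abs=0.01)

    def test_linearity_of_amplitudes(self, small_table):
        base = default_encoding_specs()
        doubled = {f: replace(s, amplitude=2 * s.amplitude)
                   for f, s in base.items()}
        ep1 = simulate_epochs(small_table, base, 8, 0.0, "sensor", 0,
                              50.0, -100.0, 700.0)
        ep2 = simulate_epochs(small_table, doubled, 8, 0.0, "sensor", 0,
                              50.0, -100.0, 700.0)
        np.testing.assert_allclose(ep2.data, 2 * ep1.data, atol=1e-12)

    def test_passive_trials_carry_no_motor_code(self, small_table):
        specs = silenced("motor")
        ep = simulate_epochs(small_table, specs, 8, 0.0, "sensor", 0,
                             50.0, -100.0, 700.0)
        passive = ~small_table.active.astype(bool).to_numpy()
        assert np.abs(ep.data[passive]).max() == 0.0
        assert np.abs(ep.data[~passive]).max() > 0.0

    def test_missing_feature_rejected(self, small_table):
        specs = default_encoding_specs()
        del specs["motor"]
        with pytest.raises(ValueError, match="missing features"):
            simulate_epochs(small_table, specs, 8, 1.0, "sensor", 0)

    def test_rt_coupling_requires_rts(self):
        table = generate_design(2, 36, 4, seed=0)  # behavior not simulated
        specs = silenced("category", rt_coupling=0.5)
        with pytest.raises(ValueError, match="RTs are missing"):
            simulate_epochs(table, specs, 8, 1.0, "sensor", 0)

    def test_seed_determinism(self, small_table):
        a = simulate_epochs(small_table, None, 8, 1.0, "sensor", 5)
        b = simulate_epochs(small_table, None, 8, 1.0, "sensor", 5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_rt_coupled_single_trial_latency_tracks_rt(self,
                                                       dispersed_rt_table):
        table = dispersed_rt_table
        specs = silenced("category", rt_coupling=1.0, amplitude=2.0)
        ep = simulate_epochs(table, specs, 8, 0.05, "sensor", 2,
                             100.0, -100.0, 900.0)
        act = table.active.astype(bool).to_numpy()
        energy = (ep.data[act] ** 2).sum(axis=1)
        peak_t = ep.times_ms[np.argmax(energy, axis=1)]
        rts = table.rt_ms.to_numpy()[act]
        assert np.corrcoef(peak_t, rts)[0, 1] > 0.5

    def test_uncoupled_latency_independent_of_rt(self, dispersed_rt_table):
        table = dispersed_rt_table
        specs = silenced("category", rt_coupling=0.0, amplitude=2.0)
        ep = simulate_epochs(table, specs, 8, 0.05, "sensor", 2,
                             100.0, -100.0, 900.0)
        act = table.active.astype(bool).to_numpy()
        energy = (ep.data[act] ** 2).sum(axis=1)
        peak_t = ep.times_ms[np.argmax(energy, axis=1)]
        rts = table.rt_ms.to_numpy()[act]
        assert abs(np.corrcoef(peak_t, rts)[0, 1]) < 0.2


class TestEpochSet:
    def test_roundtrip_is_bit_identical(self, small_epochs, tmp_path):
        path = tmp_path / "epochs.h5"
        small_epochs.save(path)
        loaded = EpochSet.load(path)
        np.testing.assert_array_equal(loaded.data, small_epochs.data)
        np.testing.assert_array_equal(loaded.times_ms, small_epochs.times_ms)
        assert loaded.space == small_epochs.space
        assert loaded.subject_id == small_epochs.subject_id

    def test_nonuniform_times_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            EpochSet(np.zeros((2, 3, 4)), np.array([0.0, 1.0, 3.0, 4.0]))

    def test_source_space_requires_coords(self):
        with pytest.raises(ValueError, match="coords"):
            EpochSet(np.zeros((2, 3, 4)), np.arange(4.0), space="source")


class TestSourceGeometry:
    def test_deterministic_and_unit_scale(self):
        a = simulate_source_geometry(50, seed=3)
        b = simulate_source_geometry(50, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (50, 3)
        assert np.linalg.norm(a, axis=1) == pytest.approx(1.0, abs=0.1)

    def test_degenerate_count_warns(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            simulate_source_geometry(1, seed=0)

    def test_source_patterns_center_on_requested_y(self, small_table):
        coords = simulate_source_geometry(120, seed=4)
        specs = silenced("position", pattern_center_y=-0.8, stability=1.0)
        ep = simulate_epochs(small_table, specs, 120, 0.0, "source", 4,
                             50.0, -100.0, 700.0, coords=coords)
        power = (ep.data ** 2).sum(axis=(0, 2))
        y_peak = coords[np.argmax(power), 1]
        assert y_peak < -0.4


class TestDiskReports:
    def test_flat_slope_centers_reports(self):
        evidence = np.repeat(np.linspace(0, 1, 8), 100)
        rep = simulate_disk_reports(evidence, slope=0.0, noise_sd=0.02,
                                    lapse_rate=0.0, seed=0)
        means = rep.groupby("evidence").angle.mean()
        assert np.allclose(means, 0.5, atol=0.02)

    def test_lapse_trials_flagged_and_excludable(self):
        evidence = np.repeat(np.linspace(0, 1, 8), 200)
        rep = simulate_disk_reports(evidence, lapse_rate=0.15, seed=1)
        assert rep.excluded.mean() == pytest.approx(0.15, abs=0.03)
        kept = rep[~rep.excluded]
        assert (kept.visibility >= 0.05).all()

    def test_invalid_lapse_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_disk_reports(np.array([0.5]), lapse_rate=1.5)

    def test_linear_mode_tracks_evidence(self):
        evidence = np.repeat(np.linspace(0, 1, 8), 100)
        rep = simulate_disk_reports(evidence, noise_sd=0.01, lapse_rate=0.0,
                                    seed=2, response="linear")
        means = rep.groupby("evidence").angle.mean()
        assert np.allclose(means.to_numpy(), np.linspace(0, 1, 8), atol=0.02)
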