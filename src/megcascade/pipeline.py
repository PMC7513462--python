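"""End-to-end orchestration: simulate a cohort, decode, summarize the cascade.

A :class:`RunConfig` pins every parameter of a run (design counts, encoding
spec, decoder and cluster-test settings, cohort size, master seed); every
randomized stage draws an independent substream of the master seed, so a run
is reproducible from the config alone.  The default problem sizes are scaled
for desk-top simulation (tens of channels, hundreds of trials, 100 Hz) rather
than full MEG scale; all of them are configurable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster_stats import cluster_test
from .decoders import ScoreSeries, peak_and_onset, temporal_decode
from .design import FEATURES, FEATURE_COLUMNS, generate_design
from .synthetic import (
    EncodingSpec,
    EpochSet,
    default_encoding_specs,
    simulate_behavior,
    simulate_epochs,
)

__all__ = [
    "RunConfig",
    "subject_seeds",
    "simulate_subject",
    "simulate_cohort",
    "cohort_temporal_scores",
    "cascade_summary",
    "run_experiment",
    "make_fixtures",
]

#: decoding path per feature: binary features are classified (AUC), the graded
#: uncertainty feature is regressed (Spearman r)
FEATURE_KIND = {
    "position": "classify",
    "identity": "classify",
    "category": "classify",
    "uncertainty": "regress",
    "motor": "classify",
}


@dataclass
class RunConfig:
    """Fully serializable description of one experiment-scale run."""

    n_subjects: int = 17
    n_blocks: int = 12
    trials_per_block: int = 40
    passive_per_block: int = 8
    n_channels: int = 20
    sfreq: float = 100.0
    tmin_ms: float = -100.0
    tmax_ms: float = 900.0
    noise_sd: float = 1.0
    space: str = "sensor"
    n_splits: int = 5
    n_perm: int = 1000
    cluster_p: float = 0.05
    subject_jitter_ms: float = 6.0
    psychometric_slope: float = 8.0
    rt_base_ms: float = 450.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def subject_seeds(master_seed: int, subject_index: int, n: int = 4) -> np.ndarray:
    """Independent, logged substreams of the master seed (all below 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), int(subject_index)])
    return ss.generate_state(n) % (2**31)


def _jittered_specs(specs: dict[str, EncodingSpec], jitter_ms: float,
                    rng: np.random.Generator,
                    subject_index: int) -> dict[str, EncodingSpec]:
    """Per-subject variation: shift each feature's whole time course by a small
    random amount and re-seed its channel pattern."""
    out = {}
    for feat, sp in specs.items():
        shift = float(rng.normal(0.0, jitter_ms)) if jitter_ms > 0 else 0.0
        out[feat] = replace(
            sp,
            onset_ms=sp.onset_ms + shift,
            peak_ms=sp.peak_ms + shift,
            offset_ms=sp.offset_ms + shift,
            pattern_seed=sp.pattern_seed + 1000 * (subject_index + 1),
        )
    return out


def simulate_subject(
    config: RunConfig,
    subject_index: int,
    spec: dict[str, EncodingSpec] | None = None,
) -> tuple[pd.DataFrame, EpochSet]:
    """Design + behavior + epochs for one simulated subject."""
    s_design, s_behav, s_epoch, s_jit = subject_seeds(config.seed, subject_index)
    table = generate_design(
        n_blocks=config.n_blocks,
        trials_per_block=config.trials_per_block,
        passive_per_block=config.passive_per_block,
        seed=int(s_design),
    )
    table = simulate_behavior(
        table,
        psychometric_slope=config.psychometric_slope,
        rt_base_ms=config.rt_base_ms,
        seed=int(s_behav),
    )
    base = spec if spec is not None else default_encoding_specs()
    jrng = np.random.default_rng(int(s_jit))
    specs = _jittered_specs(base, config.subject_jitter_ms, jrng, subject_index)
    epochs = simulate_epochs(
        table,
        spec=specs,
        n_channels=config.n_channels,
        noise_sd=config.noise_sd,
        space=config.space,
        seed=int(s_epoch),
        sfreq=config.sfreq,
        tmin_ms=config.tmin_ms,
        tmax_ms=config.tmax_ms,
        subject_id=f"S{subject_index:02d}",
    )
    return table, epochs


def simulate_cohort(
    config: RunConfig,
    spec: dict[str, EncodingSpec] | None = None,
) -> list[tuple[pd.DataFrame, EpochSet]]:
    return [simulate_subject(config, i, spec) for i in range(config.n_subjects)]


def active_target(table: pd.DataFrame, feature: str) -> np.ndarray:
    active = table["active"].astype(bool)
    return table.loc[active, FEATURE_COLUMNS[feature]].to_numpy(float)


def active_epochs(epochs: EpochSet, table: pd.DataFrame) -> EpochSet:
    active = table["active"].astype(bool).to_numpy()
    return EpochSet(epochs.data[active], epochs.times_ms, epochs.space,
                    epochs.coords, epochs.subject_id)


def cohort_temporal_scores(
    cohort: list[tuple[pd.DataFrame, EpochSet]],
    features=FEATURES,
    n_splits: int = 5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """subjects x time decoding-score arrays per feature (active trials)."""
    out: dict[str, list[np.ndarray]] = {f: [] for f in features}
    for table, epochs in cohort:
        ep = active_epochs(epochs, table)
        for feat in features:
            series = temporal_decode(
                ep, active_target(table, feat), kind=FEATURE_KIND[feat],
                n_splits=n_splits, seed=seed, feature=feat,
            )
            out[feat].append(series.scores)
    return {f: np.vstack(v) for f, v in out.items()}


def cascade_summary(
    scores: dict[str, np.ndarray],
    times_ms: np.ndarray,
    n_perm: int = 1000,
    cluster_p: float = 0.05,
    seed: int = 0,
    smooth: int = 5,
) -> pd.DataFrame:
    """Group peak and onset latency per feature.

    The peak is taken from the subject-mean score curve — lightly smoothed
    with a ``smooth``-sample moving average to stabilize the argmax of flat
    tops, then refined by parabolic interpolation; the onset is the start of
    the first significant cluster of the one-sample sign-flip test across
    subjects.
    """
    rows = []
    for feat, arr in scores.items():
        chance = 0.5 if FEATURE_KIND[feat] == "classify" else 0.0
        res = cluster_test(arr, chance=chance, n_perm=n_perm,
                           cluster_p=cluster_p, seed=seed, tail=1)
        mask = res.significant_mask(0.05)
        mean_scores = arr.mean(axis=0)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            pad = smooth // 2
            padded = np.pad(mean_scores, pad, mode="edge")
            mean_scores = np.convolve(padded, kernel, mode="valid")
        mean_curve = ScoreSeries(mean_scores, times_ms, "mean", chance,
                                 folds=0, feature=feat)
        onset, peak = peak_and_onset(mean_curve, mask, interpolate=True)
        rows.append({"feature": feat, "onset_ms": onset, "peak_ms": peak,
                     "peak_score": float(arr.mean(axis=0).max()),
                     "chance": chance})
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Simulate a cohort and produce the cascade report.

    Returns the per-feature subjects x time score arrays, the group
    peak/onset table and a provenance record; optionally writes everything
    under ``out_dir``.
    """
    cohort = simulate_cohort(config)
    scores = cohort_temporal_scores(cohort, n_splits=config.n_splits,
                                    seed=config.seed)
    times = cohort[0][1].times_ms
    summary = cascade_summary(scores, times, n_perm=config.n_perm,
                              cluster_p=config.cluster_p, seed=config.seed)
    provenance = {
        "config": dataclasses.asdict(config),
        "n_subjects": config.n_subjects,
        "times_ms": [float(times[0]), float(times[-1])],
        "features": list(FEATURES),
    }
    report = {"scores": scores, "times_ms": times, "summary": summary,
              "provenance": provenance}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "cascade_summary.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        for feat, arr in scores.items():
            pd.DataFrame(arr, columns=times).to_csv(
                out / f"scores_{feat}.csv", index=False)
    return report


def make_fixtures(scale: str = "tiny", seed: int = 0):
    """Packaged synthetic datasets.

    ``tiny`` (6 channels, 72 trials, 3 subjects, 100 Hz) for fast end-to-end
    checks; ``default`` at the scale of the modeled experiment (40 blocks,
    1920 trials, 250 Hz).
    """
    if scale == "tiny":
        cfg = RunConfig(n_subjects=3, n_blocks=2, trials_per_block=36,
                        passive_per_block=4, n_channels=6, sfreq=100.0,
                        tmin_ms=-100.0, tmax_ms=700.0, seed=seed)
    elif scale == "default":
        cfg = RunConfig(n_subjects=17, n_blocks=40, trials_per_block=48,
                        passive_per_block=8, n_channels=306, sfreq=250.0,
                        tmin_ms=-300.0, tmax_ms=1500.0, seed=seed)
    else:
        raise ValueError("scale must be 'tiny' or 'default'")
    return cfg, simulate_cohort(cfg)


# ---------------------------------------------------------------------------
# Validation studies: parameter-recovery and calibration simulations that
# exercise the full stack under known ground truth.  Problem sizes are the
# package's desk-scale defaults; every study takes a master seed.
# ---------------------------------------------------------------------------

PLANTED_PEAKS_MS = {"position": 120.0, "identity": 225.0, "category": 370.0,
                    "uncertainty": 590.0, "motor": 604.0}


def cascade_recovery_study(seed: int = 0, n_subjects: int = 17,
                           n_perm: int = 500) -> pd.DataFrame:
    """Recover the planted cascade from a simulated cohort.

    Returns the group summary with planted peaks and deviations attached.
    """
    cfg = RunConfig(n_subjects=n_subjects, seed=seed)
    cohort = simulate_cohort(cfg)
    scores = cohort_temporal_scores(cohort, n_splits=cfg.n_splits, seed=cfg.seed)
    summary = cascade_summary(scores, cohort[0][1].times_ms, n_perm=n_perm,
                              cluster_p=cfg.cluster_p, seed=cfg.seed)
    summary["planted_peak_ms"] = summary["feature"].map(PLANTED_PEAKS_MS)
    summary["peak_deviation_ms"] = summary["peak_ms"] - summary["planted_peak_ms"]
    return summary


def tg_signature_study(n_replicates: int = 20, seed: int = 0,
                       n_trials: int = 60, noise_sd: float = 0.5,
                       threshold: float = 0.8) -> pd.DataFrame:
    """Row/diagonal duration ratios for the maintain vs dynamic hierarchies.

    Each replicate simulates a trial ensemble of each architecture, runs the
    decoders' temporal generalization on the unit activations, thresholds the
    score matrix, and compares the mean row duration with the diagonal
    duration: stable self-recurrence predicts a ratio near 1 (square TG),
    rotational maintenance a small ratio (diagonal TG).
    """
    from .archsim import build_architecture, predicted_tg
    from .tg import generalization_durations

    rows = []
    for kind in ("maintain", "dynamic"):
        arch = build_architecture(kind, n_layers=5)
        for rep in range(n_replicates):
            tg, _ = predicted_tg(arch, n_trials=n_trials, noise_sd=noise_sd,
                                 seed=seed + 7919 * rep, feature=1,
                                 n_steps=8)
            mask = tg.scores >= threshold
            dur = generalization_durations(tg, mask)
            rows.append({"kind": kind, "replicate": rep, "ratio": dur["ratio"],
                         "diagonal_duration": dur["diagonal_duration_ms"],
                         "mean_row_duration": dur["mean_row_duration_ms"]})
    return pd.DataFrame(rows)


def cluster_fwer_study(n_cohorts: int = 200, n_subjects: int = 8,
                       n_elements: int = 50, n_perm: int = 512,
                       alpha: float = 0.05, seed: int = 0) -> dict:
    """Family-wise false-positive rate of the sign-flip cluster test on pure
    Gaussian null cohorts (time-chain adjacency)."""
    from .cluster_stats import cluster_test

    rng = np.random.default_rng(seed)
    false_pos = 0
    for c in range(n_cohorts):
        values = rng.standard_normal((n_subjects, n_elements))
        res = cluster_test(values, chance=0.0, n_perm=n_perm, seed=int(
            rng.integers(2**31)), tail=1)
        if res.p_values.size and res.p_values.min() < alpha:
            false_pos += 1
    return {"fwer": false_pos / n_cohorts, "n_cohorts": n_cohorts,
            "alpha": alpha}


def _disk_cohort_scores(n_subjects: int, response: str, seed: int,
                        n_per_level: int = 12, slope: float = 10.0,
                        noise_sd: float = 0.35, n_levels: int = 8,
                        n_morphs: int = 4):
    """Per-subject mean CV r of the linear and sigmoid report models."""
    from .psychometrics import crossval_compare, prepare_reports
    from .synthetic import simulate_disk_reports

    r_lin, r_sig = [], []
    for s in range(n_subjects):
        rl, rs = [], []
        for m in range(n_morphs):
            levels = np.repeat(np.linspace(0, 1, n_levels), n_per_level)
            rep = simulate_disk_reports(levels, slope=slope, noise_sd=noise_sd,
                                        lapse_rate=0.15,
                                        seed=seed + 101 * s + 13 * m,
                                        response=response)
            rep = rep[~rep.excluded]
            x, y = prepare_reports(rep.evidence.to_numpy(),
                                   rep.angle.to_numpy())
            cv = crossval_compare(x, y, n_splits=5, seed=seed + m,
                                  scoring="pooled")
            rl.append(cv["mean_linear"])
            rs.append(cv["mean_sigmoid"])
        r_lin.append(np.nanmean(rl))
        r_sig.append(np.nanmean(rs))
    return np.array(r_lin), np.array(r_sig)


def psychometric_discrimination_study(n_cohorts: int = 100,
                                      n_subjects: int = 8,
                                      seed: int = 0) -> dict:
    """How often does cross-validated model comparison prefer the sigmoid?

    Cohorts of sigmoid-generated disk reports should prefer the sigmoid model
    (one-sided signed-rank p < 0.05) nearly always; linear-generated cohorts
    should essentially never do so.
    """
    from .psychometrics import compare_across_subjects

    out = {}
    for response in ("sigmoid", "linear"):
        prefer = 0
        for c in range(n_cohorts):
            r_lin, r_sig = _disk_cohort_scores(
                n_subjects, response, seed=seed + 997 * c)
            res = compare_across_subjects(r_sig, r_lin, alternative="greater")
            if res["p_value"] < 0.05:
                prefer += 1
        out[response] = prefer / n_cohorts
    return out


#: rt-coupling gains planted along the hierarchy in the recovery study
RT_GAIN_PROFILE = {"position": 0.0, "identity": 0.0, "category": 0.5,
                   "uncertainty": 0.5, "motor": 1.0}


def rt_gain_recovery_study(n_replicates: int = 100, seed: int = 0,
                           gains: dict[str, float] | None = None,
                           n_blocks: int = 6, n_channels: int = 16,
                           sfreq: float = 50.0) -> pd.DataFrame:
    """Recover planted latency-per-RT gains from RT-binned generalization.

    Each replicate simulates one subject with the given per-feature
    rt-coupling gains, RT dispersion independent of stimulus ambiguity
    (so quantile bins stay class-balanced for every target), and recovers
    each gain as the regression slope of template-matched per-bin latency
    shifts on bin mean RT.
    """
    from .design import generate_design
    from .rt_dynamics import rt_binned_tg, shifts_by_template
    from .synthetic import (default_encoding_specs, simulate_behavior,
                            simulate_epochs)

    if gains is None:
        gains = dict(RT_GAIN_PROFILE)
    base = default_encoding_specs()
    rows = []
    for rep in range(n_replicates):
        ss = np.random.SeedSequence([int(seed), rep]).generate_state(3) % (2**31)
        specs = {f: replace(s, rt_coupling=gains.get(f, 0.0))
                 for f, s in base.items()}
        table = generate_design(n_blocks, 40, 8, seed=int(ss[0]))
        table = simulate_behavior(table, seed=int(ss[1]),
                                  uncertainty_weight=0.0, noise_sd=0.6)
        epochs = simulate_epochs(table, specs, n_channels, 1.0, "sensor",
                                 int(ss[2]), sfreq, -100.0, 900.0)
        ep = active_epochs(epochs, table)
        act = table[table.active.astype(bool)]
        rts = act.rt_ms.to_numpy()
        for feat in gains:
            if feat == "uncertainty":
                u = act.uncertainty.to_numpy()
                target = np.where(u > np.median(u), 1.0, -1.0)
            else:
                target = active_target(table, feat)
            sp = base[feat]
            window = (max(sp.onset_ms, 150.0), 660.0)
            res = rt_binned_tg(ep, target, rts, n_bins=4, n_splits=5,
                               seed=rep, train_window_ms=window,
                               max_lag_ms=240.0)
            sh = shifts_by_template(res["aligned"], res["lags_ms"])
            ok = np.isfinite(sh)
            slope = (np.polyfit(res["bin_mean_rt_ms"][ok], sh[ok], 1)[0]
                     if ok.sum() >= 2 else np.nan)
            rows.append({"replicate": rep, "feature": feat,
                         "injected": gains[feat], "recovered": slope})
    return pd.DataFrame(rows)


def readout_interaction_study(n_replicates: int = 20, n_subjects: int = 17,
                              seed: int = 0) -> pd.DataFrame:
    """Linear-early / sigmoid-late categorization yields a positive
    trend x window interaction.

    The category code is planted as two components: an early stage whose
    amplitude is linear in signed evidence and a late stage with an
    all-or-none (report-signed, saturated) readout.  Held-out classifier
    probabilities are related to evidence in an early and a late window; the
    sigmoid-vs-linear CV advantage should grow from the early to the late
    window across subjects.
    """
    from .design import generate_design
    from .readout_shape import (prediction_by_evidence, trend_comparison,
                                trend_interaction)
    from .synthetic import (EncodingSpec, default_encoding_specs,
                            simulate_behavior, simulate_epochs)

    windows = [(200.0, 400.0), (500.0, 700.0)]
    rows = []
    for rep in range(n_replicates):
        trends = []
        for subj in range(n_subjects):
            ss = np.random.SeedSequence(
                [int(seed), rep, subj]).generate_state(3) % (2**31)
            specs = default_encoding_specs()
            specs["category"] = [
                EncodingSpec(150.0, 300.0, 450.0, 0.9, pattern_seed=13,
                             stability=0.8, readout="linear"),
                EncodingSpec(450.0, 600.0, 750.0, 0.9, pattern_seed=131,
                             stability=0.8, readout="sigmoid",
                             readout_gain=10.0),
            ]
            table = generate_design(6, 40, 8, seed=int(ss[0]))
            table = simulate_behavior(table, seed=int(ss[1]))
            epochs = simulate_epochs(table, specs, 20, 1.0, "sensor",
                                     int(ss[2]), 100.0, -100.0, 900.0)
            ep = active_epochs(epochs, table)
            act = table[table.active.astype(bool)]
            evidence = act.letter_evidence.to_numpy()
            target = act.category_code.to_numpy()
            _, preds = prediction_by_evidence(ep, target, evidence, windows,
                                             n_splits=5, seed=int(ss[2]))
            trends.append(trend_comparison(preds, n_splits=5, seed=int(ss[2])))
        inter = trend_interaction(trends)
        rows.append({"replicate": rep,
                     "mean_interaction": inter["mean_interaction"],
                     "p_value": inter["p_value"]})
    return pd.DataFrame(rows)
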