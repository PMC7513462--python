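"""Synthetic MEG epochs and behavior with controllable feature codes.

The generator plants, on top of Gaussian sensor noise, one spatio-temporal
code per trial feature.  Each code is

    ``amplitude * readout(trial) * envelope(t - shift_trial) * pattern(t)``

where

* ``envelope`` is a smooth, compactly supported bump (half-Hann rise from
  onset to peak, half-Hann fall from peak to offset),
* ``pattern(t)`` is a unit-norm channel pattern that is static for
  ``stability = 1`` and rotates smoothly within a random 2D channel subspace
  as stability decreases (the generative mechanism behind diagonal temporal
  generalization),
* ``readout`` maps the trial's signed evidence to the code's signed
  amplitude, either linearly or through a saturating (sigmoidal) nonlinearity,
* ``shift_trial = rt_coupling * (rt - mean rt)`` couples the code's latency to
  the trial's reaction time.

In source space, channel patterns are localized along the postero-anterior
(y) axis with a Gaussian profile centered at ``pattern_center_y``, so that
spatial decoding recovers the planted anatomical ordering of the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .design import FEATURES

__all__ = [
    "EncodingSpec",
    "EpochSet",
    "default_encoding_specs",
    "simulate_behavior",
    "simulate_epochs",
    "simulate_source_geometry",
    "simulate_disk_reports",
]


@dataclass(frozen=True)
class EncodingSpec:
    """Generative parameters of one feature code.

    Times are in ms relative to stimulus onset; ``amplitude`` is in units of
    the sensor noise standard deviation.
    """

    onset_ms: float
    peak_ms: float
    offset_ms: float
    amplitude: float
    pattern_seed: int = 0
    pattern_center_y: float = 0.0
    stability: float = 1.0
    readout: str = "linear"
    rt_coupling: float = 0.0
    #: sigmoid readout steepness (in units of signed evidence)
    readout_gain: float = 6.0
    #: at stability 0 the channel pattern completes a full rotation in this
    #: many ms; the rotation slows proportionally as stability -> 1
    rotation_period_ms: float = 250.0
    #: abstract codes share the channel pattern between active and passive
    #: character sets; non-abstract (pixel-specific) codes do not transfer
    abstract: bool = True
    #: restrict the code to active trials (e.g. late decision-related stages)
    active_only: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_ms < self.peak_ms < self.offset_ms):
            raise ValueError("need onset < peak < offset")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.stability <= 1.0:
            raise ValueError("stability must lie in [0, 1]")
        if self.readout not in ("linear", "sigmoid"):
            raise ValueError("readout must be 'linear' or 'sigmoid'")
        if self.rt_coupling < 0:
            raise ValueError("rt_coupling must be >= 0")


def default_encoding_specs() -> dict[str, EncodingSpec]:
    """Default cascade: sequential, partially overlapping feature codes.

    Peak latencies (120 / 225 / 370 / 590 / 604 ms for position, identity,
    category, uncertainty and button press) and decodability windows follow
    the group-level latencies the analyses are meant to recover; amplitudes
    are calibrated so that default decoding peaks span the strong-to-weak
    range typical of sensor-level MEG decoding (position strong, category
    weak).  Patterns are partially dynamic (stability < 1), producing
    diagonal-leaning temporal generalization.
    """
    return {
        "position": EncodingSpec(40.0, 120.0, 700.0, 1.6, pattern_seed=11,
                                 pattern_center_y=-0.8, stability=0.85),
        "identity": EncodingSpec(120.0, 225.0, 845.0, 0.7, pattern_seed=12,
                                 pattern_center_y=-0.4, stability=0.8),
        "category": EncodingSpec(150.0, 370.0, 940.0, 0.6, pattern_seed=13,
                                 pattern_center_y=0.0, stability=0.75),
        "uncertainty": EncodingSpec(270.0, 590.0, 1200.0, 0.8, pattern_seed=14,
                                    pattern_center_y=0.4, stability=0.75),
        "motor": EncodingSpec(400.0, 604.0, 1100.0, 1.2, pattern_seed=15,
                              pattern_center_y=0.8, stability=0.8,
                              readout="sigmoid"),
    }


@dataclass
class EpochSet:
    """Trials x channels x time array with a time axis and channel metadata."""

    data: np.ndarray
    times_ms: np.ndarray
    space: str = "sensor"
    coords: np.ndarray | None = None
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis length mismatch")
        steps = np.diff(self.times_ms)
        if steps.size and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("times must be strictly increasing with uniform step")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.space not in ("sensor", "source"):
            raise ValueError("space must be 'sensor' or 'source'")
        if self.space == "source" and self.coords is None:
            raise ValueError("source-space epochs require coords")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, float)
            if self.coords.shape != (self.data.shape[1], 3):
                raise ValueError("coords must be channels x 3")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def sfreq(self) -> float:
        return 1000.0 / float(self.times_ms[1] - self.times_ms[0])

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochSet":
        mask = (self.times_ms >= tmin_ms) & (self.times_ms <= tmax_ms)
        return EpochSet(self.data[:, :, mask], self.times_ms[mask],
                        self.space, self.coords, self.subject_id)

    def save(self, path) -> None:
        """Write to an HDF5 container (datasets: data, times_ms, coords)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times_ms", data=self.times_ms)
            f.attrs["space"] = self.space
            f.attrs["subject_id"] = self.subject_id
            if self.coords is not None:
                f.create_dataset("coords", data=self.coords)

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            coords = f["coords"][()] if "coords" in f else None
            return cls(f["data"][()], f["times_ms"][()],
                       str(f.attrs["space"]), coords, str(f.attrs["subject_id"]))

    def to_mne(self):
        """Export to an mne.EpochsArray (requires mne)."""
        import mne

        info = mne.create_info(
            [f"CH{i:03d}" for i in range(self.n_channels)], self.sfreq, "mag"
        )
        return mne.EpochsArray(
            self.data, info, tmin=self.times_ms[0] / 1000.0, verbose="error"
        )


def default_times(sfreq: float = 250.0, tmin_ms: float = -300.0,
                  tmax_ms: float = 1500.0) -> np.ndarray:
    step = 1000.0 / sfreq
    n = int(round((tmax_ms - tmin_ms) / step)) + 1
    return tmin_ms + step * np.arange(n)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_behavior(
    table: pd.DataFrame,
    psychometric_slope: float = 8.0,
    rt_base_ms: float = 450.0,
    stage_delays: Mapping[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    uncertainty_weight: float = 1.0,
) -> pd.DataFrame:
    """Fill reports and reaction times for the active trials of a design.

    The probability of reporting "letter" is a logistic function of letter
    evidence; the reaction time is ``rt_base`` plus one positive delay per
    processing stage, each scaling with trial uncertainty (ambiguous stimuli
    take longer; ``uncertainty_weight`` scales this dependence, 0 makes RT
    variation independent of the stimulus) and log-normally dispersed with
    ``noise_sd``.

    On ambiguous trials the category code is redefined by the report, and the
    motor code follows ``mapping * identity * reported category``.
    """
    if rt_base_ms <= 0:
        raise ValueError("rt_base_ms must be positive")
    if stage_delays is None:
        stage_delays = {"position": 0.0, "identity": 40.0, "category": 60.0,
                        "uncertainty": 50.0, "motor": 50.0}
    table = table.copy()
    active = table["active"].astype(bool).to_numpy()
    if not active.any():
        raise ValueError("design contains no active trials")
    rng = np.random.default_rng(seed)

    le = table.loc[active, "letter_evidence"].to_numpy(float)
    p_letter = _sigmoid(psychometric_slope * (le - 0.5))
    report = np.where(rng.random(le.size) < p_letter, 1.0, -1.0)

    n_steps = int(table["evidence_step"].max())
    step = table.loc[active, "evidence_step"].to_numpy(int)
    ambiguous = (step != 1) & (step != n_steps)
    stim_cat = np.where(le > 0.5, 1.0, -1.0)
    category = np.where(ambiguous, report, stim_cat)
    correct = np.where(ambiguous, np.nan, (report == stim_cat).astype(float))

    u = table.loc[active, "uncertainty"].to_numpy(float)
    rt = np.full(le.size, float(rt_base_ms))
    for feat in FEATURES:
        scale = float(stage_delays.get(feat, 0.0))
        if scale == 0.0:
            continue
        noise = np.exp(rng.normal(-0.5 * noise_sd**2, noise_sd, le.size))
        rt = rt + scale * (1.0 + uncertainty_weight * u) * noise
    if np.any(rt <= 0):
        raise RuntimeError("non-positive reaction time generated")

    table.loc[active, "report"] = report
    table.loc[active, "category_code"] = category
    table.loc[active, "motor_code"] = (
        table.loc[active, "mapping"].to_numpy(float)
        * table.loc[active, "identity_code"].to_numpy(float)
        * category
    )
    table.loc[active, "rt_ms"] = rt
    table.loc[active, "correct"] = correct
    return table


def _envelope(times_ms: np.ndarray, onset: float, peak: float,
              offset: float, fall_mix: float = 0.5) -> np.ndarray:
    """Smooth asymmetric bump with a transient peak and a sustained tail.

    Half-Hann rise from onset to peak.  The fall is a mixture of two
    half-Hann components: a fast one mirroring the rise (so the curvature at
    the peak is comparable on both sides and the peak latency is well
    defined) and a slow one reaching zero at ``offset`` (so decodability
    outlasts the transient, as late significance windows do).
    """
    env = np.zeros_like(times_ms, float)
    rise = (times_ms >= onset) & (times_ms <= peak)
    fall = (times_ms > peak) & (times_ms <= offset)
    env[rise] = 0.5 * (1.0 - np.cos(np.pi * (times_ms[rise] - onset) / (peak - onset)))
    dt_fall = times_ms[fall] - peak
    fast = 0.5 * (1.0 + np.cos(np.pi * np.minimum(dt_fall / (peak - onset), 1.0)))
    slow = 0.5 * (1.0 + np.cos(np.pi * dt_fall / (offset - peak)))
    env[fall] = fall_mix * fast + (1.0 - fall_mix) * slow
    return env


def _pattern_pair(rng: np.random.Generator, n_channels: int,
                  coords: np.ndarray | None, center_y: float,
                  spread: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal channel patterns, spatially localized in source space."""
    weight = np.ones(n_channels)
    if coords is not None:
        y = coords[:, 1]
        weight = np.exp(-0.5 * ((y - center_y) / spread) ** 2)
    p1 = rng.standard_normal(n_channels) * weight
    p2 = rng.standard_normal(n_channels) * weight
    p1 = p1 / np.linalg.norm(p1)
    p2 = p2 - (p2 @ p1) * p1
    p2 = p2 / np.linalg.norm(p2)
    return p1, p2


def _phase(times_ms: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Rotation angle of the channel pattern at each (trial-relative) time.

    A full rotation takes ``rotation_period_ms / (1 - stability)`` ms; at
    stability 1 the pattern is static.
    """
    if spec.stability >= 1.0:
        return np.zeros_like(times_ms, float)
    rate = (1.0 - spec.stability) / spec.rotation_period_ms
    return 2.0 * np.pi * rate * (times_ms - spec.onset_ms)


def _pattern_over_time(p1: np.ndarray, p2: np.ndarray, times_ms: np.ndarray,
                       spec: EncodingSpec) -> np.ndarray:
    """channels x time pattern; rotates in span(p1, p2) when stability < 1."""
    theta = _phase(times_ms, spec)
    return p1[:, None] * np.cos(theta)[None, :] + p2[:, None] * np.sin(theta)[None, :]


def _signed_evidence(table: pd.DataFrame, feature: str) -> np.ndarray:
    """Per-trial signed evidence driving each feature's code."""
    if feature == "position":
        return table["position_code"].to_numpy(float)
    if feature == "identity":
        return table["identity_code"].to_numpy(float)
    if feature == "category":
        # signed letter evidence in [-1, 1]; sign may be flipped on ambiguous
        # trials where the report disagrees with the stimulus
        s = 2.0 * table["letter_evidence"].to_numpy(float) - 1.0
        rep = table["category_code"].to_numpy(float)
        return np.abs(s) * rep
    if feature == "uncertainty":
        u = table["uncertainty"].to_numpy(float)
        umax = np.nanmax(u) if np.nanmax(u) > 0 else 1.0
        return 2.0 * (u / umax) - 1.0
    if feature == "motor":
        s = 2.0 * table["letter_evidence"].to_numpy(float) - 1.0
        motor = table["motor_code"].to_numpy(float)
        return np.abs(s) * motor
    raise KeyError(feature)


def _readout(spec: EncodingSpec, s: np.ndarray) -> np.ndarray:
    if spec.readout == "linear":
        return s
    g = spec.readout_gain
    return np.tanh(g * s) / np.tanh(g)


def simulate_epochs(
    table: pd.DataFrame,
    spec: Mapping[str, EncodingSpec | Sequence[EncodingSpec]] | None = None,
    n_channels: int = 20,
    noise_sd: float = 1.0,
    space: str = "sensor",
    seed: int = 0,
    sfreq: float = 250.0,
    tmin_ms: float = -300.0,
    tmax_ms: float = 1500.0,
    coords: np.ndarray | None = None,
    subject_id: str = "S00",
) -> EpochSet:
    """Synthesize epochs for every trial of a design table.

    ``spec`` maps each of the five features to an :class:`EncodingSpec` (or a
    list of them, whose contributions sum — e.g. an early linear plus a late
    sigmoidal categorization stage).  Passive trials never carry a motor code;
    ``active_only`` specs are silenced on passive trials, and non-``abstract``
    specs use an independent channel pattern for the passive character set.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if spec is None:
        spec = default_encoding_specs()
    missing = [f for f in FEATURES if f not in spec]
    if missing:
        raise ValueError(f"encoding spec missing features: {missing}")

    times = default_times(sfreq, tmin_ms, tmax_ms)
    n = len(table)
    rng = np.random.default_rng(seed)
    if space == "source" and coords is None:
        coords = simulate_source_geometry(n_channels, seed=seed)
    use_coords = coords if space == "source" else None

    active = table["active"].astype(bool).to_numpy()
    rts = table["rt_ms"].to_numpy(float)
    rt_mean = np.nanmean(rts[active]) if np.isfinite(rts[active]).any() else 0.0

    signal = np.zeros((n, n_channels, times.size))
    for feature in FEATURES:
        components = spec[feature]
        if isinstance(components, EncodingSpec):
            components = [components]
        for comp in components:
            if comp.amplitude == 0:
                continue
            v = _readout(comp, _signed_evidence(table, feature))
            if feature == "motor" or comp.active_only:
                v = np.where(active, v, 0.0)
            v = np.where(np.isfinite(v), v, 0.0)

            shifts = np.zeros(n)
            if comp.rt_coupling > 0:
                need = active & (v != 0)
                if not np.all(np.isfinite(rts[need])):
                    raise ValueError(
                        f"rt_coupling > 0 for {feature!r} but RTs are missing"
                    )
                shifts[need] = comp.rt_coupling * (rts[need] - rt_mean)

            prng = np.random.default_rng(
                np.random.SeedSequence([int(seed), int(comp.pattern_seed)])
            )
            p1, p2 = _pattern_pair(prng, n_channels, use_coords,
                                   comp.pattern_center_y)
            if not comp.abstract:
                # pixel-specific passive pattern: orthogonal to the active
                # one, so an abstract-code decoder cannot transfer to it
                q1, q2 = _pattern_pair(prng, n_channels, use_coords,
                                       comp.pattern_center_y)
                for p in (p1, p2):
                    q1 = q1 - (q1 @ p) * p
                q1 = q1 / np.linalg.norm(q1)
                for p in (p1, p2, q1):
                    q2 = q2 - (q2 @ p) * p
                q2 = q2 / np.linalg.norm(q2)
            else:
                q1, q2 = p1, p2

            # a per-trial latency shift delays the whole code: the envelope
            # *and* the pattern trajectory run on trial time t - shift
            if np.any(shifts != 0):
                trial_times = times[None, :] - shifts[:, None]
            else:
                trial_times = np.broadcast_to(times, (n, times.size))
            env = np.stack(
                [_envelope(tt, comp.onset_ms, comp.peak_ms, comp.offset_ms)
                 for tt in trial_times]
            ) if np.any(shifts != 0) else np.broadcast_to(
                _envelope(times, comp.onset_ms, comp.peak_ms, comp.offset_ms),
                (n, times.size),
            )
            amp = comp.amplitude * v[:, None] * env  # trials x time
            if comp.stability >= 1.0:
                a1 = np.where(active[:, None], p1[None], q1[None])
                signal += amp[:, None, :] * a1[:, :, None]
            else:
                rate = 2.0 * np.pi * (1.0 - comp.stability) / comp.rotation_period_ms
                theta = rate * (trial_times - comp.onset_ms)
                cosa = amp * np.cos(theta)
                sina = amp * np.sin(theta)
                a1 = np.where(active[:, None], p1[None], q1[None])
                a2 = np.where(active[:, None], p2[None], q2[None])
                signal += cosa[:, None, :] * a1[:, :, None]
                signal += sina[:, None, :] * a2[:, :, None]

    data = signal + noise_sd * rng.standard_normal(signal.shape)
    return EpochSet(data, times, space=space, coords=use_coords,
                    subject_id=subject_id)


def simulate_source_geometry(n_sources: int, seed: int = 0,
                             jitter: float = 0.02) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice).

    Axis conventions follow head coordinates: column 1 is the postero-anterior
    (y) axis along which the encoding specs place their pattern centers.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if n_sources < 10:
        warnings.warn(
            f"n_sources={n_sources} gives a degenerate source geometry",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    i = np.arange(n_sources) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_sources)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    pts = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.cos(phi), np.sin(phi) * np.sin(theta)]
    )
    pts = pts + jitter * rng.standard_normal(pts.shape)
    return pts


def simulate_disk_reports(
    evidence: np.ndarray,
    slope: float = 10.0,
    noise_sd: float = 0.05,
    lapse_rate: float = 0.15,
    seed: int = 0,
    visibility_floor: float = 0.05,
    response: str = "sigmoid",
) -> pd.DataFrame:
    """Continuous disk reports (normalized angle + visibility radius).

    The normalized report angle is a logistic function of evidence
    (``response="sigmoid"``, the categorical-percept regime) or the evidence
    itself (``response="linear"``, the veridical-report control) plus
    Gaussian noise.  A ``lapse_rate`` fraction of trials are "absent-like":
    random angle and near-zero visibility; the exclusion flag marks any trial
    whose visibility falls below ``visibility_floor``.
    """
    evidence = np.asarray(evidence, float)
    if np.any((evidence < 0) | (evidence > 1)):
        raise ValueError("evidence must lie in [0, 1]")
    if not 0.0 <= lapse_rate <= 1.0:
        raise ValueError("lapse_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = evidence.size
    if response == "sigmoid":
        mean_angle = _sigmoid(slope * (evidence - 0.5))
    elif response == "linear":
        mean_angle = evidence
    else:
        raise ValueError("response must be 'sigmoid' or 'linear'")
    angle = mean_angle + noise_sd * rng.standard_normal(n)
    angle = np.clip(angle, 0.0, 1.0)
    visibility = rng.uniform(0.3, 1.0, n)
    lapse = rng.random(n) < lapse_rate
    angle[lapse] = rng.random(lapse.sum())
    visibility[lapse] = rng.uniform(0.0, 0.8 * visibility_floor, lapse.sum())
    return pd.DataFrame(
        {
            "evidence": evidence,
            "angle": angle,
            "visibility": visibility,
            "excluded": visibility < visibility_floor,
        }
    )
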