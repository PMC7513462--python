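"""Discrete linear dynamical systems for candidate recurrent hierarchies.

A hierarchy of L layers is simulated as

    X[t+1] = A X[t] + B U[t]

where A decomposes into a binary diagonal maintenance matrix R, a
feedforward shift matrix F between consecutive layers, and a skip matrix S
into the last layer, combined with weights (w_R, w_F, w_S).  The input U is a
transient square pulse connected only to the first layer.  Units are laid out
as (layer, feature, phase) slots: layer l *generates* feature l (the
generation chain is the part of F linking unit (l, l) to (l+1, l+1)), and the
four candidate architectures differ in what happens afterwards:

- ``broadcast``: feedforward only; every feature propagates up the hierarchy
  (F on all slots, plus S skips into the last layer), nothing is maintained.
- ``maintain``:  each layer maintains its own feature through stable
  self-recurrence (R); low-level features are not propagated.
- ``dynamic``:   each layer keeps its feature alive in *changing* activity: a
  two-unit, 90-degrees-per-step rotation inside the layer preserves the
  information while the unit-space pattern rotates.
- ``hybrid``:    broadcast + dynamic maintenance combined.

``predicted_tg`` feeds trial ensembles of each architecture's activations to
the decoding stack: stable maintenance yields square temporal-generalization
matrices, dynamic maintenance diagonal ones.  ``delay_experiment`` withholds
one stage's output (freezing its state) for a configurable number of steps,
shifting every downstream latency by exactly that delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import EpochSet

__all__ = [
    "Architecture",
    "SimResult",
    "build_architecture",
    "simulate",
    "predicted_decoding",
    "predicted_tg",
    "delay_experiment",
]

KINDS = ("broadcast", "maintain", "dynamic", "hybrid")


@dataclass
class Architecture:
    A: np.ndarray
    B: np.ndarray
    layer_of: np.ndarray
    feature_of: np.ndarray
    kind: str
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_layers: int = 0
    n_features: int = 0

    @property
    def n_units(self) -> int:
        return self.A.shape[0]

    def units_of(self, layer: int | None = None,
                 feature: int | None = None) -> np.ndarray:
        """Indices of units in a given layer and/or encoding a given feature
        (1-based, matching hierarchical level)."""
        sel = np.ones(self.n_units, bool)
        if layer is not None:
            sel &= self.layer_of == layer
        if feature is not None:
            sel &= self.feature_of == feature
        return np.flatnonzero(sel)


@dataclass
class SimResult:
    activations: np.ndarray  # units x (n_steps + 1), t = 0 .. n_steps
    input: np.ndarray
    n_steps: int
    arch: Architecture | None = None


def _rotation_uses(kind: str) -> bool:
    return kind in ("dynamic", "hybrid")


def build_architecture(
    kind: str,
    n_layers: int = 5,
    units_per_layer: int | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Architecture:
    """Assemble the connectivity for one of the four candidate hierarchies.

    Each of the ``n_layers`` layers has one slot per feature (feature l is
    generated at layer l); rotation-based kinds use two units (phases) per
    slot.  ``units_per_layer`` only overrides the number of *feature slots*
    per layer and defaults to ``n_layers``.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown architecture kind {kind!r}; choose from {KINDS}")
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    n_features = units_per_layer or n_layers
    w_R, w_F, w_S = weights
    phases = 2 if _rotation_uses(kind) else 1

    # unit bookkeeping: index (layer, feature, phase), all 1-based layers
    index = {}
    layer_of, feature_of = [], []
    for l in range(1, n_layers + 1):
        for f in range(1, n_features + 1):
            for ph in range(phases):
                index[(l, f, ph)] = len(layer_of)
                layer_of.append(l)
                feature_of.append(f)
    n_units = len(layer_of)
    A = np.zeros((n_units, n_units))

    def gen_edges():
        """Generation chain: layer l's own feature drives layer l+1's."""
        for l in range(1, n_layers):
            if l + 1 <= n_features:
                yield index[(l + 1, l + 1, 0)], index[(l, l, 0)]

    def prop_edges():
        """Full shift: every represented feature moves one layer up."""
        for l in range(1, n_layers):
            for f in range(1, min(l, n_features) + 1):
                yield index[(l + 1, f, 0)], index[(l, f, 0)]

    def skip_edges():
        """Skip connections from every earlier layer into the last layer."""
        for l in range(1, n_layers - 1):
            for f in range(1, min(l, n_features) + 1):
                yield index[(n_layers, f, 0)], index[(l, f, 0)]

    for i, j in gen_edges():
        A[i, j] = w_F
    if kind in ("broadcast", "hybrid"):
        for i, j in prop_edges():
            A[i, j] = w_F
        for i, j in skip_edges():
            A[i, j] += w_S

    if kind == "maintain":
        for l in range(1, n_layers + 1):
            if l <= n_features:
                i = index[(l, l, 0)]
                A[i, i] = w_R
    elif _rotation_uses(kind):
        # 90-degree rotation per step within each layer's own-feature slot
        for l in range(1, n_layers + 1):
            if l <= n_features:
                a = index[(l, l, 0)]
                b = index[(l, l, 1)]
                A[a, a] += 0.0
                A[a, b] += -w_R
                A[b, a] += w_R

    B = np.zeros((n_units, 1))
    B[index[(1, 1, 0)], 0] = 1.0

    radius = float(np.max(np.abs(np.linalg.eigvals(A)))) if n_units else 0.0
    if radius > 1.0 + 1e-6:
        warnings.warn(
            f"spectral radius {radius:.3f} > 1; activations will be explosive",
            RuntimeWarning,
        )
    return Architecture(A=A, B=B, layer_of=np.array(layer_of),
                        feature_of=np.array(feature_of), kind=kind,
                        weights=tuple(weights), n_layers=n_layers,
                        n_features=n_features)


def _input_series(input_steps, n_steps: int) -> np.ndarray:
    U = np.zeros(n_steps)
    for t in input_steps:
        if 0 <= t < n_steps:
            U[int(t)] = 1.0
    return U


def simulate(arch: Architecture, input_steps=(1,), n_steps: int = 8) -> SimResult:
    """Iterate X[t+1] = A X[t] + B U[t] from X[0] = 0.

    ``input_steps`` are the time indices at which the unit square pulse is on
    (the stimulus flash); activations are returned for t = 0 .. n_steps.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    U = _input_series(input_steps, n_steps)
    X = np.zeros((arch.n_units, n_steps + 1))
    for t in range(n_steps):
        X[:, t + 1] = arch.A @ X[:, t] + arch.B[:, 0] * U[t]
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("simulation diverged (non-finite activations)")
    return SimResult(activations=X, input=U, n_steps=n_steps, arch=arch)


def predicted_decoding(sim: SimResult, threshold_frac: float = 1e-6) -> dict:
    """Which feature is decodable in which layer at which time step.

    A feature counts as decodable in a layer when any of that layer's units
    assigned to it exceeds ``threshold_frac`` of the global peak activation.
    Returns the (features x layers x time) activation magnitudes and the
    boolean decodability mask.
    """
    arch = sim.arch
    if arch is None:
        raise ValueError("SimResult carries no architecture")
    X = np.abs(sim.activations)
    peak = X.max()
    thr = threshold_frac * peak if peak > 0 else np.inf
    n_t = X.shape[1]
    act = np.zeros((arch.n_features, arch.n_layers, n_t))
    for f in range(1, arch.n_features + 1):
        for l in range(1, arch.n_layers + 1):
            units = arch.units_of(layer=l, feature=f)
            if units.size:
                act[f - 1, l - 1] = X[units].max(axis=0)
    return {"activation": act, "decodable": act > thr,
            "aggregate": act.max(axis=1)}


def predicted_tg(
    arch: Architecture,
    n_trials: int = 40,
    noise_sd: float = 0.1,
    seed: int = 0,
    feature: int = 1,
    input_steps=(1,),
    n_steps: int = 8,
    n_splits: int = 5,
):
    """Temporal generalization predicted by an architecture.

    Simulates an ensemble of trials whose feature code takes both signs,
    adds observation noise on the units encoding ``feature``, and runs the
    decoders' TG analysis on those activations.
    """
    from .tg import tg_matrix  # local import to avoid a cycle

    if n_trials < 20:
        raise ValueError("n_trials must be >= 20")
    clean = simulate(arch, input_steps, n_steps).activations
    units = np.flatnonzero(arch.feature_of == feature)
    if units.size == 0:
        raise ValueError(f"architecture has no units for feature {feature}")
    rng = np.random.default_rng(seed)
    codes = np.where(np.arange(n_trials) % 2 == 0, 1.0, -1.0)
    rng.shuffle(codes)
    data = codes[:, None, None] * clean[None, units, :]
    data = data + noise_sd * rng.standard_normal(data.shape)
    epochs = EpochSet(data, np.arange(n_steps + 1, dtype=float),
                      space="sensor", subject_id=f"{arch.kind}")
    return tg_matrix(epochs, codes, kind="classify", n_splits=n_splits,
                     seed=seed, feature=f"feature{feature}"), codes


def delay_experiment(
    arch: Architecture,
    layer,
    delay_steps,
    insert_at,
    n_steps: int,
    input_steps=(1,),
) -> SimResult:
    """Withhold one or more stages' output for a configurable number of steps.

    From ``insert_at`` (inclusive) the given layer is frozen — its units keep
    their state but neither update nor propagate — for ``delay_steps`` steps,
    after which normal dynamics resume.  Downstream latencies shift by exactly
    the delay; upstream layers are untouched.  ``delay_steps = 0`` reproduces
    the plain simulation.  Passing equal-length sequences for ``layer``,
    ``delay_steps`` and ``insert_at`` schedules several stage delays in one
    run; downstream of all of them, the delays compose additively.
    """
    if np.isscalar(layer):
        schedule = [(int(layer), int(delay_steps), int(insert_at))]
    else:
        schedule = [(int(l), int(d), int(a))
                    for l, d, a in zip(layer, delay_steps, insert_at)]
    for l, d, a in schedule:
        if not 0 <= a < n_steps:
            raise ValueError("insert_at must lie within the simulation")
        if a + d > n_steps:
            raise ValueError("delay extends past the end of the simulation")
        if not (arch.layer_of == l).any():
            raise ValueError(f"no units in layer {l}")
    U = _input_series(input_steps, n_steps)
    X = np.zeros((arch.n_units, n_steps + 1))
    for t in range(n_steps):
        frozen_units = np.zeros(arch.n_units, bool)
        for l, d, a in schedule:
            if a <= t < a + d:
                frozen_units |= arch.layer_of == l
        if frozen_units.any():
            A_t = arch.A.copy()
            A_t[:, frozen_units] = 0.0  # nothing reads from a frozen stage
        else:
            A_t = arch.A
        nxt = A_t @ X[:, t] + arch.B[:, 0] * U[t]
        nxt[frozen_units] = X[frozen_units, t]
        X[:, t + 1] = nxt
    return SimResult(activations=X, input=U, n_steps=n_steps, arch=arch)
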