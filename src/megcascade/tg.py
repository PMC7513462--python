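"""Temporal generalization: train-at-t / test-at-t' decoding matrices.

A decoder fit at training time t (including its train-fold standardization)
is evaluated on held-out trials at every test time t'.  A square region of
above-chance scores indicates a stable neural code; a narrow diagonal
indicates a dynamically rotating code.  Duration metrics compare the extent
of the significant diagonal (how long *some* decoder works) with the mean
row extent (how long *one* decoder keeps working).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .decoders import (
    ScoreSeries,
    _auc_stack,
    _check_target,
    _spearman_stack,
    _new_model,
    _standardize_params,
    decision_values,
    fit_fold_models,
)
from .synthetic import EpochSet

__all__ = [
    "TGMatrix",
    "tg_matrix",
    "generalization_durations",
    "cross_condition_generalize",
]


@dataclass
class TGMatrix:
    """Train-time x test-time decoding scores on a shared time axis."""

    scores: np.ndarray
    times_ms: np.ndarray
    metric: str
    chance: float
    feature: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.scores.shape != (self.times_ms.size, self.times_ms.size):
            raise ValueError("TG matrix must be square on the shared time axis")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.scores)


def tg_matrix(
    epochs: EpochSet,
    target: np.ndarray,
    kind: str = "classify",
    n_splits: int = 5,
    seed: int = 0,
    feature: str = "",
) -> TGMatrix:
    """Cross-validated temporal generalization matrix.

    Within each fold, the model (and scaler) trained at t is applied wholesale
    to held-out trials at every t'; scores are fold-averaged.  With shared
    folds and seed the diagonal reproduces :func:`temporal_decode`.
    """
    y = _check_target(target, kind)
    folds, W, B, MU, SD = fit_fold_models(epochs, y, kind, n_splits, seed)
    n_t = epochs.data.shape[2]
    all_t = np.arange(n_t)
    fold_scores = np.full((len(folds), n_t, n_t), np.nan)
    for k, (_, te) in enumerate(folds):
        X_te = epochs.data[te]
        y_te = y[te]
        dv = np.empty((X_te.shape[0], n_t, n_t))
        for t in range(n_t):
            dv[:, t, :] = decision_values(X_te, W[k, t], B[k, t], MU[k, t],
                                          SD[k, t], all_t)
        if kind == "classify":
            fold_scores[k] = _auc_stack(dv.reshape(len(te), -1), y_te).reshape(
                n_t, n_t)
        else:
            fold_scores[k] = _spearman_stack(dv.reshape(len(te), -1),
                                             y_te).reshape(n_t, n_t)
    scores = np.nanmean(fold_scores, axis=0)
    return TGMatrix(
        scores=scores,
        times_ms=epochs.times_ms,
        metric="AUC" if kind == "classify" else "spearman_r",
        chance=0.5 if kind == "classify" else 0.0,
        feature=feature,
        subject_id=epochs.subject_id,
    )


def _run_containing(mask: np.ndarray, idx: int) -> int:
    """Length of the contiguous True run containing position ``idx``."""
    if not mask[idx]:
        return 0
    lo = idx
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = idx
    while hi < mask.size - 1 and mask[hi + 1]:
        hi += 1
    return hi - lo + 1


def generalization_durations(tg: TGMatrix, sig_mask: np.ndarray) -> dict:
    """Row vs diagonal durations of above-chance generalization.

    For each training time with a significant diagonal sample, the row
    duration is the contiguous significant run of test times containing the
    diagonal.  The diagonal duration is the total significant extent of the
    diagonal.  Durations are in ms (sample count x time step).
    """
    sig_mask = np.asarray(sig_mask, bool)
    if sig_mask.shape != tg.scores.shape:
        raise ValueError("sig_mask shape must match the TG matrix")
    n_t = tg.times_ms.size
    dt = float(tg.times_ms[1] - tg.times_ms[0]) if n_t > 1 else 0.0
    diag = np.diag(sig_mask)
    row_durations = np.array(
        [_run_containing(sig_mask[t], t) * dt for t in range(n_t)]
    )
    diagonal_duration = float(diag.sum() * dt)
    valid = diag
    mean_row = float(row_durations[valid].mean()) if valid.any() else 0.0
    ratio = mean_row / diagonal_duration if diagonal_duration > 0 else np.nan
    return {
        "row_durations_ms": row_durations,
        "mean_row_duration_ms": mean_row,
        "diagonal_duration_ms": diagonal_duration,
        "ratio": ratio,
    }


def cross_condition_generalize(
    train_epochs: EpochSet,
    train_target: np.ndarray,
    test_epochs: EpochSet,
    test_target: np.ndarray,
    kind: str = "classify",
    feature: str = "",
) -> ScoreSeries:
    """Train on one condition (e.g. all active trials), test on a disjoint one
    (e.g. passive trials with distinct characters), per time sample.

    Standardization statistics come from the training set only.
    """
    if train_epochs.data.shape[1] != test_epochs.data.shape[1]:
        raise ValueError("train and test epochs differ in channel count")
    if train_epochs.times_ms.size != test_epochs.times_ms.size or not np.allclose(
        train_epochs.times_ms, test_epochs.times_ms
    ):
        raise ValueError("train and test epochs must share the time axis")
    y_tr = _check_target(train_target, kind)
    y_te = _check_target(test_target, kind)
    n_t = train_epochs.times_ms.size
    scores = np.full(n_t, np.nan)
    for t in range(n_t):
        Xt = train_epochs.data[:, :, t]
        mu, sd = _standardize_params(Xt)
        model = _new_model(kind)
        model.fit((Xt - mu) / sd, y_tr)
        Z_te = (test_epochs.data[:, :, t] - mu) / sd
        if kind == "classify":
            dv = model.decision_function(Z_te)
            scores[t] = _auc_stack(dv[:, None], y_te)[0]
        else:
            scores[t] = spearmanr(model.predict(Z_te), y_te).statistic
    return ScoreSeries(
        scores=scores,
        axis=train_epochs.times_ms,
        metric="AUC" if kind == "classify" else "spearman_r",
        chance=0.5 if kind == "classify" else 0.0,
        folds=1,
        feature=feature,
        subject_id=test_epochs.subject_id,
    )
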