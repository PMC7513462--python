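"""Cross-validated temporal and spatial decoding with leakage-safe scaling.

Decoders are l2-regularized linear models at the library defaults (logistic
regression with C = 1 for binary targets, ridge regression with alpha = 1 for
continuous targets).  At every time sample (temporal decoding) or every
channel/source (spatial decoding) a fresh model is fit inside a seeded
stratified K-fold; channels are standardized by the *training fold's* mean and
standard deviation only.  Classifier performance is summarized by a rank-based
AUC (mid-rank tie handling), regressor performance by a Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold

from .synthetic import EpochSet

__all__ = [
    "ScoreSeries",
    "score_auc",
    "temporal_decode",
    "spatial_decode",
    "peak_and_onset",
    "normalize_by_peak",
    "fit_fold_models",
]


@dataclass
class ScoreSeries:
    """Decoding scores over time (temporal) or over channels (spatial)."""

    scores: np.ndarray
    axis: np.ndarray
    metric: str
    chance: float
    folds: int
    feature: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.axis = np.asarray(self.axis)


def score_auc(decision_values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC: P(score+ > score-) + 0.5 P(tie)."""
    dv = np.asarray(decision_values, float)
    y = np.asarray(labels)
    pos = y > 0
    n_pos = int(pos.sum())
    n_neg = dv.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(dv)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _auc_stack(dv: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized AUC along axis 0 of ``dv`` (trials x ...)."""
    pos = np.asarray(labels) > 0
    n_pos = int(pos.sum())
    n_neg = dv.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(dv, axis=0)
    return (ranks[pos].sum(axis=0) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _spearman_stack(dv: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Spearman r between each column of ``dv`` and ``y``."""
    r_dv = rankdata(dv, axis=0)
    r_y = rankdata(np.asarray(y, float))
    r_dv = r_dv - r_dv.mean(axis=0)
    r_y = r_y - r_y.mean()
    denom = np.sqrt((r_dv**2).sum(axis=0) * (r_y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.tensordot(r_y, r_dv, axes=(0, 0)) / denom
    return out


def _make_splitter(kind: str, n_splits: int, seed: int):
    if kind == "classify":
        return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return KFold(n_splits=n_splits, shuffle=True, random_state=seed)


def _check_target(target: np.ndarray, kind: str) -> np.ndarray:
    y = np.asarray(target, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    if kind == "classify":
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("classification target must be binary (+1/-1)")
    return y


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    # relative tolerance: a numerically-constant channel has sd ~ eps * |mu|
    dead = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-variance channel(s) in training fold; "
            "excluded from the fit",
            RuntimeWarning,
        )
        sd = np.where(dead, 1.0, sd)
    return mu, sd


def _new_model(kind: str):
    if kind == "classify":
        return LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    return Ridge(alpha=1.0)


def fit_fold_models(
    epochs: EpochSet,
    target: np.ndarray,
    kind: str = "classify",
    n_splits: int = 5,
    seed: int = 0,
    train_idx_list: list[np.ndarray] | None = None,
):
    """Fit one decoder per (fold, time sample); the reusable core of temporal
    decoding, temporal generalization and the RT-binned analyses.

    Returns ``(folds, W, B, MU, SD)`` where ``folds`` is a list of
    (train_idx, test_idx) pairs and the arrays are (n_folds, n_times,
    n_channels) weights / standardization statistics and (n_folds, n_times)
    intercepts.  Held-out trials never touch the fitted weights or the
    standardization statistics.
    """
    y = _check_target(target, kind)
    X = epochs.data
    n, n_ch, n_t = X.shape
    if y.size != n:
        raise ValueError("target length must match number of trials")
    if train_idx_list is not None:
        folds = [(tr, np.setdiff1d(np.arange(n), tr)) for tr in train_idx_list]
    else:
        splitter = _make_splitter(kind, n_splits, seed)
        folds = list(splitter.split(np.zeros(n), y if kind == "classify" else None))
    W = np.zeros((len(folds), n_t, n_ch))
    B = np.zeros((len(folds), n_t))
    MU = np.zeros((len(folds), n_t, n_ch))
    SD = np.ones((len(folds), n_t, n_ch))
    for k, (tr, _) in enumerate(folds):
        y_tr = y[tr]
        if kind == "classify" and np.unique(y_tr).size < 2:
            raise ValueError("single-class training fold; stratification failed")
        for t in range(n_t):
            Xt = X[tr, :, t]
            mu, sd = _standardize_params(Xt)
            Z = (Xt - mu) / sd
            model = _new_model(kind)
            model.fit(Z, y_tr)
            W[k, t] = model.coef_.ravel()
            B[k, t] = float(np.atleast_1d(model.intercept_)[0]) if hasattr(
                model, "intercept_") else 0.0
            MU[k, t] = mu
            SD[k, t] = sd
    return folds, W, B, MU, SD


def decision_values(X_test: np.ndarray, w: np.ndarray, b: float,
                    mu: np.ndarray, sd: np.ndarray,
                    time_idx: np.ndarray) -> np.ndarray:
    """Apply one fitted decoder to test trials at the given time samples."""
    Z = (X_test[:, :, time_idx] - mu[None, :, None]) / sd[None, :, None]
    return (Z * w[None, :, None]).sum(axis=1) + b


def temporal_decode(
    epochs: EpochSet,
    target: np.ndarray,
    kind: str = "classify",
    n_splits: int = 5,
    seed: int = 0,
    feature: str = "",
) -> ScoreSeries:
    """One cross-validated decoder per time sample, scored on held-out trials.

    AUC (chance 0.5) for binary targets, Spearman r (chance 0) for continuous
    targets; scores are averaged over folds.
    """
    y = _check_target(target, kind)
    folds, W, B, MU, SD = fit_fold_models(epochs, y, kind, n_splits, seed)
    n_t = epochs.data.shape[2]
    fold_scores = np.full((len(folds), n_t), np.nan)
    for k, (_, te) in enumerate(folds):
        X_te = epochs.data[te]
        y_te = y[te]
        for t in range(n_t):
            dv = decision_values(X_te, W[k, t], B[k, t], MU[k, t], SD[k, t],
                                 np.array([t]))[:, 0]
            if kind == "classify":
                fold_scores[k, t] = score_auc(dv, y_te)
            else:
                fold_scores[k, t] = _spearman_stack(dv[:, None], y_te)[0]
    scores = np.nanmean(fold_scores, axis=0)
    return ScoreSeries(
        scores=scores,
        axis=epochs.times_ms,
        metric="AUC" if kind == "classify" else "spearman_r",
        chance=0.5 if kind == "classify" else 0.0,
        folds=len(folds),
        feature=feature,
        subject_id=epochs.subject_id,
    )


def spatial_decode(
    epochs: EpochSet,
    target: np.ndarray,
    kind: str = "classify",
    window_ms: tuple[float, float] = (0.0, 1500.0),
    n_splits: int = 5,
    seed: int = 0,
    feature: str = "",
) -> ScoreSeries:
    """One cross-validated decoder per channel/source.

    Each channel's feature vector is its time course within ``window_ms``
    (stimulus-locked by default); the CV / standardization contract matches
    :func:`temporal_decode`.
    """
    y = _check_target(target, kind)
    lo, hi = window_ms
    if lo < epochs.times_ms[0] or hi > epochs.times_ms[-1]:
        raise ValueError("window outside epoch time range")
    tmask = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    X = epochs.data[:, :, tmask]
    n, n_ch, _ = X.shape
    splitter = _make_splitter(kind, n_splits, seed)
    folds = list(splitter.split(np.zeros(n), y if kind == "classify" else None))
    fold_scores = np.full((len(folds), n_ch), np.nan)
    for k, (tr, te) in enumerate(folds):
        for c in range(n_ch):
            Xc = X[tr, c, :]
            mu, sd = _standardize_params(Xc)
            model = _new_model(kind)
            model.fit((Xc - mu) / sd, y[tr])
            Z_te = (X[te, c, :] - mu) / sd
            if kind == "classify":
                dv = model.decision_function(Z_te)
                fold_scores[k, c] = score_auc(dv, y[te])
            else:
                dv = model.predict(Z_te)
                fold_scores[k, c] = spearmanr(dv, y[te]).statistic
    scores = np.nanmean(fold_scores, axis=0)
    axis = epochs.coords[:, 1] if epochs.coords is not None else np.arange(n_ch)
    return ScoreSeries(
        scores=scores,
        axis=axis,
        metric="AUC" if kind == "classify" else "spearman_r",
        chance=0.5 if kind == "classify" else 0.0,
        folds=len(folds),
        feature=feature,
        subject_id=epochs.subject_id,
    )


def peak_and_onset(
    series: ScoreSeries,
    sig_mask: np.ndarray | None = None,
    interpolate: bool = False,
) -> tuple[float | None, float]:
    """Onset (first time of the first significant cluster) and peak latency.

    The peak is the argmax of the score curve, optionally refined by a
    3-point parabolic interpolation; the onset is ``None`` when no significant
    cluster is supplied or present.
    """
    t = np.asarray(series.axis, float)
    s = series.scores
    i = int(np.argmax(s))
    peak = t[i]
    if interpolate and 0 < i < s.size - 1:
        y0, y1, y2 = s[i - 1], s[i], s[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            peak = t[i] + 0.5 * (y0 - y2) / denom * (t[1] - t[0])
    onset = None
    if sig_mask is not None:
        sig_mask = np.asarray(sig_mask, bool)
        if sig_mask.any():
            onset = float(t[int(np.argmax(sig_mask))])
    return onset, float(peak)


def normalize_by_peak(series_set: list[ScoreSeries]) -> list[ScoreSeries]:
    """Rescale each curve to (score - chance) / (peak - chance); max = 1."""
    out = []
    for s in series_set:
        peak = float(np.max(s.scores))
        if peak <= s.chance:
            raise ValueError(
                f"curve for {s.feature!r} never exceeds chance; "
                "peak normalization undefined"
            )
        out.append(
            ScoreSeries(
                scores=(s.scores - s.chance) / (peak - s.chance),
                axis=s.axis,
                metric=f"{s.metric}_norm",
                chance=0.0,
                folds=s.folds,
                feature=s.feature,
                subject_id=s.subject_id,
            )
        )
    return out
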