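"""Latency-vs-reaction-time coupling of decodable representations.

Decoders are trained at every time sample on all included trials; held-out
trials are then split into reaction-time quantile bins and scored at every
test time.  Re-indexing the per-bin generalization scores relative to the
training time and averaging across training times yields, for each bin, a
lag curve whose peak measures how much that bin's neural code is shifted
relative to the average processing speed.  Regressing the per-bin peak
latency on the bin's mean RT gives the delay-per-ms-of-RT slope for each
feature; slopes are tested against zero across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decoders import _auc_stack, _check_target, decision_values, fit_fold_models
from .psychometrics import compare_across_subjects
from .synthetic import EpochSet


def _smooth(c: np.ndarray, width: int) -> np.ndarray:
    """Edge-padded moving average (zero padding would dent both curve ends
    identically across bins and bias any cross-curve alignment toward 0)."""
    if width <= 1:
        return c
    pad = width // 2
    padded = np.pad(c, pad, mode="edge")
    return np.convolve(padded, np.ones(width) / width, mode="valid")[: c.size]

__all__ = [
    "rt_binned_tg",
    "peak_latency_from_aligned",
    "shifts_by_template",
    "latency_rt_slope",
]


def rt_binned_tg(
    epochs: EpochSet,
    target: np.ndarray,
    rts: np.ndarray,
    n_bins: int = 4,
    n_splits: int = 5,
    seed: int = 0,
    train_window_ms: tuple[float, float] | None = None,
    max_lag_ms: float | None = None,
) -> dict:
    """Per-RT-bin generalization curves aligned to training time.

    Decoders are trained on all trials (within the CV); held-out decision
    values are pooled across folds, split by RT quantile, and scored (AUC) per
    (bin, train time, test time).  Scores are then averaged along the
    diagonals, i.e. as a function of lag = test time - train time.

    Trials must all carry an RT; quantile bins partition them.
    """
    y = _check_target(target, "classify")
    rts = np.asarray(rts, float)
    if rts.size != y.size or not np.all(np.isfinite(rts)):
        raise ValueError("RTs must be available for all included trials")
    edges = np.quantile(rts, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, rts, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            raise ValueError(f"RT bin {b} is empty")

    times = epochs.times_ms
    if train_window_ms is not None:
        lo, hi = train_window_ms
        train_mask = (times >= lo) & (times <= hi)
    else:
        train_mask = np.ones(times.size, bool)
    train_idx = np.flatnonzero(train_mask)

    folds, W, B, MU, SD = fit_fold_models(epochs, y, "classify", n_splits, seed)
    n = y.size
    n_t = times.size
    all_t = np.arange(n_t)
    # pooled held-out decision values: trials x train times x test times
    dv_pool = np.zeros((n, train_idx.size, n_t))
    for k, (_, te) in enumerate(folds):
        X_te = epochs.data[te]
        for j, t in enumerate(train_idx):
            dv_pool[te, j, :] = decision_values(X_te, W[k, t], B[k, t],
                                                MU[k, t], SD[k, t], all_t)

    dt = float(times[1] - times[0])
    # only lags for which *every* train time has a valid test sample enter the
    # aligned average: partial coverage creates an unshifted edge artifact
    # shared across bins that swamps small latency shifts
    full_cover = min(int(train_idx.min()), int(n_t - 1 - train_idx.max()))
    if max_lag_ms is None:
        max_lag = full_cover
    else:
        max_lag = min(int(round(max_lag_ms / dt)), full_cover)
    max_lag = max(max_lag, 1)
    lags = np.arange(-max_lag, max_lag + 1)

    scores = np.full((n_bins, train_idx.size, n_t), np.nan)
    bin_rt = np.zeros(n_bins)
    for b in range(n_bins):
        sel = bins == b
        bin_rt[b] = rts[sel].mean()
        if np.unique(y[sel]).size < 2:
            continue  # score missing for a single-class bin
        dv = dv_pool[sel].reshape(int(sel.sum()), -1)
        scores[b] = _auc_stack(dv, y[sel]).reshape(train_idx.size, n_t)

    aligned = np.full((n_bins, lags.size), np.nan)
    for li, lag in enumerate(lags):
        test_pos = train_idx + lag
        ok = (test_pos >= 0) & (test_pos < n_t)
        if not ok.any():
            continue
        vals = scores[:, ok, :][:, np.arange(ok.sum()), test_pos[ok]]
        aligned[:, li] = np.nanmean(vals, axis=1)

    return {
        "aligned": aligned,
        "lags_ms": lags * dt,
        "bin_mean_rt_ms": bin_rt,
        "bin_assignments": bins,
        "train_times_ms": times[train_idx],
    }


def peak_latency_from_aligned(
    aligned: np.ndarray,
    lags_ms: np.ndarray,
    smooth: int = 3,
    method: str = "argmax",
) -> np.ndarray:
    """Per-bin peak lag of the aligned curve.

    ``method="argmax"``: curves are smoothed with a ``smooth``-sample moving
    average to stabilize the argmax, and the peak is refined by 3-point
    parabolic interpolation.  ``method="com"``: centroid of the upper half of
    the smoothed curve (lags where it exceeds halfway between its minimum and
    maximum) — a lower-variance, shift-equivariant latency estimate for flat
    or noisy peaks.
    """
    aligned = np.atleast_2d(np.asarray(aligned, float))
    lags_ms = np.asarray(lags_ms, float)
    dt = lags_ms[1] - lags_ms[0]
    out = np.full(aligned.shape[0], np.nan)
    for b, curve in enumerate(aligned):
        ok = np.isfinite(curve)
        if not ok.any():
            continue
        c = _smooth(np.where(ok, curve, np.nanmin(curve)), smooth)
        if method == "com":
            lo, hi = float(c.min()), float(c.max())
            if hi <= lo:
                continue
            w = np.maximum(c - (lo + 0.5 * (hi - lo)), 0.0)
            out[b] = float((lags_ms * w).sum() / w.sum())
            continue
        if method != "argmax":
            raise ValueError("method must be 'argmax' or 'com'")
        i = int(np.argmax(c))
        peak = lags_ms[i]
        if 0 < i < c.size - 1:
            y0, y1, y2 = c[i - 1], c[i], c[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                peak += 0.5 * (y0 - y2) / denom * dt
        out[b] = peak
    return out


def shifts_by_template(
    aligned: np.ndarray,
    lags_ms: np.ndarray,
    max_shift_ms: float = 250.0,
    smooth: int = 3,
) -> np.ndarray:
    """Per-bin latency shift by template matching across bins.

    Each bin's (smoothed, mean-centered) aligned curve is cross-correlated
    with the mean curve of the *other* bins over integer-sample shifts up to
    ``max_shift_ms``; the best shift is refined by parabolic interpolation.
    The leave-one-out template avoids the zero-shift bias a bin's own noise
    would otherwise induce, and the resulting shifts are rescaled by
    (B-1)/B so they are relative to the all-bin average.  Unlike a
    thresholded peak or centroid, template matching does not attenuate small
    shifts at low SNR, so it is the estimator of choice for slope (gain)
    recovery.  Positive = later than average.
    """
    aligned = np.atleast_2d(np.asarray(aligned, float))
    n_bins = aligned.shape[0]
    lags_ms = np.asarray(lags_ms, float)
    dt = lags_ms[1] - lags_ms[0]

    def prep(c):
        ok = np.isfinite(c)
        return _smooth(np.where(ok, c, np.nanmin(c)), smooth)

    curves = np.stack([prep(c) for c in aligned])
    k = max(1, int(round(max_shift_ms / dt)))
    out = np.full(n_bins, np.nan)
    for b, c in enumerate(curves):
        if n_bins > 1:
            template = np.delete(curves, b, axis=0).mean(axis=0)
        else:
            template = curves.mean(axis=0)
        xc = np.full(2 * k + 1, -np.inf)
        for j, d in enumerate(range(-k, k + 1)):
            if d >= 0:
                a, t_ = c[d:], template[: template.size - d]
            else:
                a, t_ = c[:d], template[-d:]
            a = a - a.mean()
            t_ = t_ - t_.mean()
            denom = np.sqrt((a**2).sum() * (t_**2).sum())
            if denom > 0:
                xc[j] = float(a @ t_) / denom
        i = int(np.argmax(xc))
        shift = (i - k) * dt
        if 0 < i < xc.size - 1 and np.all(np.isfinite(xc[i - 1 : i + 2])):
            y0, y1, y2 = xc[i - 1], xc[i], xc[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                shift += 0.5 * (y0 - y2) / denom * dt
        out[b] = shift
    if n_bins > 1:
        out *= (n_bins - 1) / n_bins  # undo leave-one-out inflation
    return out


def latency_rt_slope(shifts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject-feature latency-vs-RT slopes and a group test per feature.

    ``shifts`` is tidy with columns (subject_id, feature, rt_bin, rt_mean_ms,
    peak_latency_ms).  The slope is the OLS regression of peak latency on bin
    mean RT (ms of latency per ms of RT).  Subjects missing bins for a feature
    are dropped for that feature.  Group test: Wilcoxon signed-rank across
    subjects against zero (reported when >= 5 subjects).
    """
    required = {"subject_id", "feature", "rt_bin", "rt_mean_ms", "peak_latency_ms"}
    if not required.issubset(shifts.columns):
        raise ValueError(f"shifts must have columns {sorted(required)}")
    rows = []
    for (subj, feat), g in shifts.groupby(["subject_id", "feature"]):
        g = g.dropna(subset=["rt_mean_ms", "peak_latency_ms"])
        if len(g) < 2:
            continue
        slope = np.polyfit(g["rt_mean_ms"], g["peak_latency_ms"], 1)[0]
        rows.append({"subject_id": subj, "feature": feat, "slope": slope})
    slopes = pd.DataFrame(rows)
    group_rows = []
    for feat, g in slopes.groupby("feature"):
        vals = g["slope"].to_numpy()
        if vals.size >= 5:
            res = compare_across_subjects(vals)
            p = res["p_value"]
        else:
            p = np.nan
        group_rows.append({"feature": feat, "mean_slope": float(vals.mean()),
                           "n_subjects": int(vals.size), "p_value": p})
    return slopes, pd.DataFrame(group_rows)
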