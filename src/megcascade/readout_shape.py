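"""Linear vs categorical readout of decoder predictions across time windows.

Cross-validated classifier probabilities (for the perceptual-category or
motor decoder, trained on data averaged within a time window) are related to
the trial's graded evidence.  Early sensory stages should yield predictions
that vary *linearly* with evidence; later decision stages should yield
all-or-none, *sigmoidal* predictions.  The trend x window interaction — how
much the sigmoid's cross-validated advantage grows from an early to a late
window — is tested across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .decoders import _check_target, _standardize_params
from .psychometrics import compare_across_subjects, crossval_compare
from .synthetic import EpochSet

__all__ = [
    "prediction_by_evidence",
    "trend_comparison",
    "trend_interaction",
]


def prediction_by_evidence(
    epochs: EpochSet,
    target: np.ndarray,
    evidence: np.ndarray,
    windows: list[tuple[float, float]],
    n_splits: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Held-out classifier probabilities by evidence level and time window.

    For each window the epoch data are averaged over time, standardized by the
    training fold, and classified with the l2 logistic model; the held-out
    probability of the positive class is recorded per trial.  Returns
    ``(curves, trial_preds)``: mean probability per (window, evidence level),
    and the tidy trial-level predictions the trend comparison consumes.
    """
    y = _check_target(target, "classify")
    evidence = np.asarray(evidence, float)
    if evidence.size != y.size or not np.all(np.isfinite(evidence)):
        raise ValueError("evidence must be defined for all trials")
    times = epochs.times_ms
    trial_rows = []
    for w, (lo, hi) in enumerate(windows):
        if lo < times[0] or hi > times[-1]:
            raise ValueError(f"window ({lo}, {hi}) outside epoch time range")
        tmask = (times >= lo) & (times <= hi)
        Xw = epochs.data[:, :, tmask].mean(axis=2)
        p_hat = np.full(y.size, np.nan)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for tr, te in skf.split(Xw, y):
            mu, sd = _standardize_params(Xw[tr])
            model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
            model.fit((Xw[tr] - mu) / sd, y[tr])
            pos = int(np.argmax(model.classes_))
            p_hat[te] = model.predict_proba((Xw[te] - mu) / sd)[:, pos]
        for i in range(y.size):
            trial_rows.append(
                {"window": w, "window_lo_ms": lo, "window_hi_ms": hi,
                 "trial": i, "evidence": evidence[i], "label": y[i],
                 "p_hat": p_hat[i]}
            )
    trial_preds = pd.DataFrame(trial_rows)
    curves = (
        trial_preds.groupby(["window", "evidence"], as_index=False)["p_hat"]
        .mean()
        .rename(columns={"p_hat": "mean_prediction"})
    )
    return curves, trial_preds


def trend_comparison(
    trial_preds: pd.DataFrame,
    n_splits: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated linear vs sigmoid fits of prediction-vs-evidence.

    Reuses the psychometric model comparison on the trial-level (evidence,
    held-out probability) pairs, separately per window.
    """
    rows = []
    for w, g in trial_preds.groupby("window"):
        cv = crossval_compare(g["evidence"].to_numpy(),
                              g["p_hat"].to_numpy(), n_splits=n_splits,
                              seed=seed)
        rows.append(
            {"window": w, "r_linear": cv["mean_linear"],
             "r_sigmoid": cv["mean_sigmoid"],
             "sigmoid_advantage": cv["mean_sigmoid"] - cv["mean_linear"]}
        )
    return pd.DataFrame(rows)


def trend_interaction(
    per_subject_trends: list[pd.DataFrame],
    early_window: int = 0,
    late_window: int | None = None,
) -> dict:
    """Trend x window interaction across subjects.

    Per subject: (r_sigmoid - r_linear) in the late window minus the same
    contrast in the early window; positive values mean the readout becomes
    more categorical over time.  Tested against zero with a signed-rank test
    when >= 5 subjects are available.
    """
    interactions = []
    for trends in per_subject_trends:
        t = trends.set_index("window")
        late = late_window if late_window is not None else int(t.index.max())
        interactions.append(
            float(t.loc[late, "sigmoid_advantage"]
                  - t.loc[early_window, "sigmoid_advantage"])
        )
    interactions = np.asarray(interactions)
    p = np.nan
    if interactions.size >= 5:
        p = compare_across_subjects(interactions,
                                    alternative="greater")["p_value"]
    return {
        "interactions": interactions,
        "mean_interaction": float(interactions.mean()),
        "p_value": p,
    }
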