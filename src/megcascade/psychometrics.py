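"""Linear vs sigmoidal evidence-to-report models under cross-validation.

Subjective reports (normalized to [0, 1]) are modeled as a function of
stimulus evidence either linearly,

    y = b1 * x + b0,

or sigmoidally,

    y = b0 + 1 / (1 + exp(-b1 * (x - b2))),

fit by least squares.  Because the two models differ in parameter count, they
are compared within a seeded K-fold cross-validation: both models are fit on
the same training points and scored by the Pearson correlation between
predicted and observed held-out responses.  Model preference is then tested
across subjects with Wilcoxon signed-rank tests.

The sigmoid slope is constrained positive (monotone increasing), which fixes
the sign ambiguity of the exponential's argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr, wilcoxon

from sklearn.model_selection import KFold

__all__ = [
    "FitResult",
    "fit_model",
    "crossval_compare",
    "compare_across_subjects",
    "prepare_reports",
]


@dataclass
class FitResult:
    model: str
    betas: np.ndarray
    cv_r: np.ndarray | None = None
    mean_r: float = np.nan
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.model == "linear":
            b0, b1 = self.betas
            return b0 + b1 * x
        b0, b1, b2 = self.betas
        return _sigmoid_model(x, b0, b1, b2)


def _sigmoid_model(x, b0, b1, b2):
    return b0 + 1.0 / (1.0 + np.exp(-b1 * (x - b2)))


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(pearsonr(a, b).statistic)


def fit_model(x: np.ndarray, y: np.ndarray, model: str) -> FitResult:
    """Least-squares fit of the linear (closed form) or sigmoidal (iterative)
    evidence-to-report model.

    Sigmoid initialization: slope from the central finite difference (times 4,
    the sigmoid's maximum-slope factor), midpoint at the central evidence
    value, baseline at min(y); bounds keep the fitted curve monotone
    increasing.  A constant response is a degenerate fit and is flagged.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n_params = 2 if model == "linear" else 3
    if x.size != y.size or x.size < n_params:
        raise ValueError("need len(x) == len(y) >= number of parameters")
    if np.ptp(y) == 0:
        warnings.warn("constant response; degenerate fit", RuntimeWarning)
        if model == "linear":
            return FitResult("linear", np.array([y[0], 0.0]), degenerate=True)
        return FitResult("sigmoid", np.array([y[0] - 0.5, 1e-6, float(np.mean(x))]),
                         degenerate=True)
    if model == "linear":
        b1, b0 = np.polyfit(x, y, 1)
        fit = FitResult("linear", np.array([b0, b1]))
    elif model == "sigmoid":
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        mid = xs.size // 2
        lo, hi = max(mid - 1, 0), min(mid + 1, xs.size - 1)
        dx = xs[hi] - xs[lo]
        slope = (ys[hi] - ys[lo]) / dx if dx > 0 else 1.0
        p0 = [float(np.min(y)), max(4.0 * slope, 0.5), float(np.median(x))]
        span = np.ptp(x) if np.ptp(x) > 0 else 1.0
        bounds = (
            [np.min(y) - 1.0, 1e-6, np.min(x) - span],
            [np.max(y) + 1.0, 1e4, np.max(x) + span],
        )
        try:
            betas, _ = curve_fit(_sigmoid_model, x, y, p0=p0, bounds=bounds,
                                 maxfev=5000)
        except RuntimeError as err:
            raise RuntimeError(
                f"sigmoid fit did not converge (n={x.size}, "
                f"y range [{np.min(y):.3g}, {np.max(y):.3g}]): {err}"
            ) from err
        fit = FitResult("sigmoid", betas)
    else:
        raise ValueError("model must be 'linear' or 'sigmoid'")
    fit.mean_r = _safe_pearson(fit.predict(x), y)
    return fit


def crossval_compare(
    x: np.ndarray,
    y: np.ndarray,
    n_splits: int = 5,
    seed: int = 0,
    scoring: str = "per_split",
) -> dict:
    """Paired held-out Pearson r for the linear and sigmoid models.

    Both models see identical splits.  With ``scoring="per_split"`` each
    fold's held-out points are correlated separately (a fold whose held-out
    responses are constant — or a singleton fold — is recorded as NaN for
    both models).  With ``scoring="pooled"`` the held-out predictions are
    collected across folds first and a single correlation per model is
    computed, which remains defined for very small point sets such as
    level-averaged psychometric curves (8 points per morph).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if x.size < 2 * n_splits and scoring == "per_split":
        raise ValueError("not enough points per split; use scoring='pooled'")
    if x.size < n_splits:
        raise ValueError("need at least one point per split")
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    r_lin = np.full(n_splits, np.nan)
    r_sig = np.full(n_splits, np.nan)
    pred_lin = np.full(x.size, np.nan)
    pred_sig = np.full(x.size, np.nan)
    for k, (tr, te) in enumerate(kf.split(x)):
        lin = fit_model(x[tr], y[tr], "linear")
        sig = fit_model(x[tr], y[tr], "sigmoid")
        pred_lin[te] = lin.predict(x[te])
        pred_sig[te] = sig.predict(x[te])
        r_lin[k] = _safe_pearson(pred_lin[te], y[te])
        r_sig[k] = _safe_pearson(pred_sig[te], y[te])
    pooled_lin = _safe_pearson(pred_lin, y)
    pooled_sig = _safe_pearson(pred_sig, y)
    if scoring == "pooled":
        mean_lin, mean_sig = pooled_lin, pooled_sig
    elif scoring == "per_split":
        mean_lin = float(np.nanmean(r_lin))
        mean_sig = float(np.nanmean(r_sig))
    else:
        raise ValueError("scoring must be 'per_split' or 'pooled'")
    return {
        "linear": r_lin,
        "sigmoid": r_sig,
        "pooled_linear": pooled_lin,
        "pooled_sigmoid": pooled_sig,
        "mean_linear": mean_lin,
        "mean_sigmoid": mean_sig,
    }


def compare_across_subjects(
    per_subject_scores_a: np.ndarray,
    per_subject_scores_b: np.ndarray | None = None,
    alternative: str = "two-sided",
) -> dict:
    """Wilcoxon signed-rank test across subjects.

    Paired (a vs b) when two score vectors are given, one-sample against zero
    (chance) otherwise.  All-zero differences yield p = 1 by convention and
    are flagged.
    """
    a = np.asarray(per_subject_scores_a, float)
    if a.size < 5:
        raise ValueError("need at least 5 subjects for the signed-rank test")
    if per_subject_scores_b is not None:
        b = np.asarray(per_subject_scores_b, float)
        if b.shape != a.shape:
            raise ValueError("paired score vectors must have the same length")
        diff = a - b
    else:
        diff = a
    if np.all(diff == 0):
        warnings.warn("all differences are zero; p = 1 by convention",
                      RuntimeWarning)
        return {"statistic": np.nan, "p_value": 1.0, "degenerate": True}
    res = wilcoxon(diff, alternative=alternative)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "degenerate": False}


def prepare_reports(evidence: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average responses within each evidence level, then normalize the
    averages to span [0, 1] (per subject, as done before model fitting)."""
    evidence = np.asarray(evidence, float)
    response = np.asarray(response, float)
    levels = np.unique(evidence)
    means = np.array([response[evidence == lv].mean() for lv in levels])
    rng_ = np.ptp(means)
    norm = (means - means.min()) / rng_ if rng_ > 0 else np.zeros_like(means)
    return levels, norm
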