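"""Mass-univariate linear encoding of the five trial features.

At every channel/source and time sample, the single-trial response y is
regressed on the n x 5 design matrix of feature codes via ordinary least
squares, beta = (X'X)^-1 X'y.  Feature columns are z-scored so betas are
comparable across features, and an intercept column is included (its beta is
not returned).  The per-subject beta maps feed the second-level sign-flip
cluster statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import FEATURES, FEATURE_COLUMNS
from .synthetic import EpochSet

__all__ = ["BetaMap", "build_design_matrix", "fit_encoding"]


@dataclass
class BetaMap:
    """features x channels x time regression coefficients."""

    betas: np.ndarray
    design_columns: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, float)
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")


def build_design_matrix(
    table: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    zscore: bool = True,
) -> np.ndarray:
    """n_trials x n_features design matrix of (optionally z-scored) codes."""
    cols = [FEATURE_COLUMNS.get(f, f) for f in features]
    X = table[cols].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite feature codes")
    if zscore:
        sd = X.std(axis=0)
        if np.any(sd == 0):
            bad = [c for c, s in zip(cols, sd) if s == 0]
            raise ValueError(f"constant design column(s): {bad}")
        X = (X - X.mean(axis=0)) / sd
    return X


def fit_encoding(
    epochs: EpochSet,
    table: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    zscore: bool = True,
    add_intercept: bool = True,
    baseline_correct: bool = True,
) -> BetaMap:
    """OLS encoding betas at every (channel, time).

    Only trials with finite codes for all requested features enter the fit
    (passive trials drop out through their missing motor code).  Epochs are
    baseline-corrected by subtracting each trial's pre-stimulus channel mean.
    A rank-deficient design raises, naming the collinear columns.
    """
    if len(table) != epochs.n_trials:
        raise ValueError("trial table and epochs are not aligned")
    cols = [FEATURE_COLUMNS.get(f, f) for f in features]
    finite = np.all(np.isfinite(table[cols].to_numpy(float)), axis=1)
    sub = table.loc[finite]
    X = build_design_matrix(sub, features, zscore=zscore)
    n, f = X.shape
    Xd = np.column_stack([X, np.ones(n)]) if add_intercept else X
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {Xd.shape[1]}); most "
            f"collinear columns: {cols[i]!r} and {cols[j]!r} "
            f"(r={corr[i, j]:.3f})"
        )

    data = epochs.data[finite]
    if baseline_correct:
        pre = epochs.times_ms < 0
        if pre.any():
            data = data - data[:, :, pre].mean(axis=2, keepdims=True)
    Y = data.reshape(n, -1)
    coef, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    betas = coef[:f].reshape(f, epochs.n_channels, epochs.times_ms.size)
    return BetaMap(betas=betas, design_columns=tuple(features),
                   subject_id=epochs.subject_id)
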