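"""Per-fold univariate feature filters.

Classification folds rank every connectome feature by the absolute Welch
(unequal-variance) two-sample t-statistic between the two training classes
and keep the top k.  Regression folds rank by the absolute Pearson
correlation between the feature and age.  The filters are ranking devices
run inside each cross-validation fold on training scans only; no degrees of
freedom or p-values are computed.

Ties in |statistic| are broken toward the smaller feature number so fold
selections are reproducible.  Features with zero variance in both groups
(or overall, for the correlation filter) score 0 rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class FilterError(ValueError):
    pass


@dataclass
class FeatureSelection:
    """Top-k features: 1-based ``selected`` numbers in rank order, plus the
    full per-feature score vector (t or r) and k."""

    selected: np.ndarray
    scores: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.selected.size != self.k:
            raise FilterError("selection size differs from k")
        if self.selected.min(initial=1) < 1 or \
                self.selected.max(initial=1) > self.scores.size:
            raise FilterError("selected feature numbers out of range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, self.k + 1),
            "feature_number": self.selected,
            "statistic": self.scores[self.selected - 1],
        })


def welch_t(group_a, group_b) -> float:
    """Unequal-variance two-sample t-statistic.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with n-1 variance
    denominators.  If both variances vanish: 0 for equal means, +/-inf
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise FilterError("each group needs at least 2 values")
    return float(_welch_t_cols(a[:, None], b[:, None])[0])


def _welch_t_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Welch t for samples-in-rows matrices."""
    diff = A.mean(axis=0) - B.mean(axis=0)
    denom = np.sqrt(A.var(axis=0, ddof=1) / A.shape[0]
                    + B.var(axis=0, ddof=1) / B.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero_denom = denom == 0
    t[zero_denom & (diff == 0)] = 0.0
    t[zero_denom & (diff > 0)] = np.inf
    t[zero_denom & (diff < 0)] = -np.inf
    return t


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """1-based feature numbers of the k largest |scores|, ties by number."""
    order = np.lexsort((np.arange(scores.size), -np.abs(scores)))
    return order[:k] + 1


def select_top_t(X: np.ndarray, labels, k: int) -> FeatureSelection:
    """Top-k features by |Welch t| between the two classes of ``labels``."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise FilterError(
            f"need exactly 2 classes in training rows, got {classes.size}")
    if not 1 <= k <= X.shape[1]:
        raise FilterError(f"k={k} outside 1..{X.shape[1]}")
    A = X[labels == classes[0]]
    B = X[labels == classes[1]]
    if len(A) < 2 or len(B) < 2:
        raise FilterError("each class needs at least 2 training scans")
    t = _welch_t_cols(A, B)
    return FeatureSelection(_top_k(t, k), t, k)


def select_top_corr(X: np.ndarray, age, k: int) -> FeatureSelection:
    """Top-k features by |Pearson r| between feature and age."""
    X = np.asarray(X, dtype=float)
    age = np.asarray(age, dtype=float)
    if age.std() == 0:
        raise FilterError("age is constant in training rows")
    if not 1 <= k <= X.shape[1]:
        raise FilterError(f"k={k} outside 1..{X.shape[1]}")
    xc = X - X.mean(axis=0)
    ac = age - age.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (ac ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = xc.T @ ac / denom
    r[denom == 0] = 0.0
    return FeatureSelection(_top_k(r, k), r, k)
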