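"""Subject-grouped leave-one-out cross-validation and significance.

The unit of cross-validation is the *subject*, not the scan: each fold
removes every scan of one subject, selects features on the remaining
training scans only, trains the model, and predicts the held-out scans.
Keeping a subject's scans together avoids "twinning" bias, the optimistic
leakage that occurs when near-identical scans of one person straddle the
train/test split.

Subject-level predictions: a classified subject takes the majority vote of
its scans (ties resolved by the sign of the summed decision values); a
regression subject's predicted age is the mean of its scan predictions.
Accuracy is counted over subjects, and its significance is the exact
binomial upper tail with chance probability 1/2 (1/K for K classes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import svm
from .filters import FeatureSelection, select_top_corr, select_top_t


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dataset

@dataclass
class GroupedDataset:
    """Scans-by-features matrix with subject identity per scan.

    ``y`` holds one value per scan (class label or age); it must be
    constant within each subject, and every subject must contribute the
    same number of scans.
    """

    X: np.ndarray
    subject_of: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.subject_of = np.asarray(self.subject_of)
        self.y = np.asarray(self.y)
        n = self.X.shape[0]
        if self.subject_of.size != n or self.y.size != n:
            raise EvaluationError("X, subject_of and y disagree on n_scans")
        counts = pd.Series(self.subject_of).value_counts()
        if counts.nunique() != 1:
            raise EvaluationError(
                "every subject must have the same number of scans")
        for s in counts.index:
            vals = np.unique(self.y[self.subject_of == s])
            if vals.size != 1:
                raise EvaluationError(
                    f"subject {s}: label/age differs across scans")

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject ids in order of first appearance."""
        _, idx = np.unique(self.subject_of, return_index=True)
        return self.subject_of[np.sort(idx)]

    def subject_y(self, subject) -> object:
        return self.y[self.subject_of == subject][0]


def _folds(data: GroupedDataset):
    """Yield (held_out_subject, train_idx, test_idx); the constructor makes
    sharing a subject across the split impossible."""
    for subject in data.subjects:
        test = np.flatnonzero(data.subject_of == subject)
        train = np.flatnonzero(data.subject_of != subject)
        assert not np.intersect1d(data.subject_of[train],
                                  [subject]).size, "twinning guard"
        yield subject, train, test


# ---------------------------------------------------------------------------
# reports

@dataclass
class FoldResult:
    held_out_subject: object
    selection: FeatureSelection
    scan_pred: np.ndarray
    scan_scores: np.ndarray
    subject_pred: object
    w: np.ndarray | None  # weights on the selected features, fold order
    b: float


@dataclass
class CVReport:
    folds: list
    subjects: np.ndarray
    truth: np.ndarray
    predicted: np.ndarray
    task: str = "classification"
    n_correct: int = 0
    accuracy: float = float("nan")
    p_value: float = float("nan")
    p_chance: float = 0.5
    slope: float = float("nan")
    intercept: float = float("nan")
    r2: float = float("nan")
    residuals: np.ndarray | None = None

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subjects,
            "truth": self.truth,
            "predicted": self.predicted,
        })

    def to_dict(self) -> dict:
        d = {
            "task": self.task,
            "subjects": [str(s) for s in self.subjects],
            "truth": np.asarray(self.truth).tolist(),
            "predicted": np.asarray(self.predicted).tolist(),
            "per_fold_selected": [f.selection.selected.tolist()
                                  for f in self.folds],
        }
        if self.task == "regression":
            d.update(slope=self.slope, intercept=self.intercept, r2=self.r2,
                     residuals=self.residuals.tolist())
        else:
            d.update(n_correct=self.n_correct, accuracy=self.accuracy,
                     p_value=self.p_value, p_chance=self.p_chance)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# significance

def binomial_tail(n_correct: int, n_trials: int, p_chance: float) -> float:
    """Exact upper-tail probability Pr(X >= n_correct), X ~ Bin(n, p).

    Computed by direct summation of binomial probabilities; no normal
    approximation is used.
    """
    if not 0 <= n_correct <= n_trials:
        raise EvaluationError(
            f"n_correct {n_correct} outside 0..{n_trials}")
    if not 0 < p_chance < 1:
        raise EvaluationError("p_chance must lie strictly in (0, 1)")
    ks = np.arange(n_correct, n_trials + 1)
    return float(np.sum(stats.binom.pmf(ks, n_trials, p_chance)))


def regression_line(predicted, true):
    """OLS of predicted age on true age: slope, intercept, R^2, residuals.

    R^2 is the squared Pearson correlation between predicted and true age;
    a perfect predictor gives slope 1, intercept 0, R^2 = 1.
    """
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.size < 3:
        raise EvaluationError("need at least 3 points")
    if np.std(true) == 0:
        raise EvaluationError("true ages are constant")
    fit = stats.linregress(true, predicted)
    residuals = predicted - (fit.slope * true + fit.intercept)
    return fit.slope, fit.intercept, fit.rvalue ** 2, residuals


# ---------------------------------------------------------------------------
# LOOCV drivers

def _majority_vote(preds: np.ndarray, scores_by_class: np.ndarray,
                   classes: np.ndarray):
    """Majority vote over a subject's scans; ties by summed scores."""
    counts = np.array([(preds == c).sum() for c in classes])
    top = np.flatnonzero(counts == counts.max())
    if top.size == 1:
        return classes[top[0]]
    summed = scores_by_class.sum(axis=0)
    best = top[np.argmax(summed[top])]
    return classes[best]


def loocv_classify(data: GroupedDataset, k: int, C: float,
                   kernel: svm.KernelSpec | None = None) -> CVReport:
    """Binary subject-grouped LOOCV with a per-fold Welch-t filter."""
    kernel = kernel or svm.KernelSpec()
    classes = np.unique(data.y)
    if classes.size != 2:
        raise EvaluationError("binary LOOCV needs exactly 2 classes")
    signs = {classes[0]: -1.0, classes[1]: 1.0}

    folds = []
    subj_pred = []
    for subject, train, test in _folds(data):
        ytr = data.y[train]
        if np.unique(ytr).size != 2:
            raise EvaluationError(
                f"fold {subject}: a class is absent from the training set")
        sel = select_top_t(data.X[train], ytr, k)
        cols = sel.selected - 1
        model = svm.train_binary_svm(
            data.X[train][:, cols],
            np.array([signs[v] for v in ytr]), C, kernel)
        scores = svm.decision_function(model, data.X[test][:, cols])
        preds = np.where(scores >= 0, classes[1], classes[0])
        vote = _majority_vote(
            preds, np.stack([-scores, scores], axis=1), classes)
        w = svm.extract_weights(model) if kernel.kind == "linear" else None
        folds.append(FoldResult(subject, sel, preds, scores, vote, w,
                                model.b))
        subj_pred.append(vote)

    subjects = data.subjects
    truth = np.array([data.subject_y(s) for s in subjects])
    predicted = np.array(subj_pred)
    n_correct = int((predicted == truth).sum())
    n = subjects.size
    return CVReport(folds=folds, subjects=subjects, truth=truth,
                    predicted=predicted, task="classification",
                    n_correct=n_correct, accuracy=n_correct / n,
                    p_value=binomial_tail(n_correct, n, 0.5), p_chance=0.5)


def loocv_multiclass(data: GroupedDataset, k: int, C: float) -> CVReport:
    """Weston-Watkins multiclass LOOCV; chance level is 1/K.

    The t-filter needs two groups, so multiclass folds rank features by the
    largest absolute Welch t over all class pairs (reduces to the binary
    filter at K = 2).
    """
    classes = np.unique(data.y)
    K = classes.size
    folds = []
    subj_pred = []
    for subject, train, test in _folds(data):
        ytr = data.y[train]
        if np.unique(ytr).size != K:
            raise EvaluationError(
                f"fold {subject}: a class is absent from the training set")
        sel = _select_top_t_multi(data.X[train], ytr, k, classes)
        cols = sel.selected - 1
        model = svm.train_multiclass_svm(data.X[train][:, cols], ytr, C)
        scores = model.scores(data.X[test][:, cols])
        preds = model.predict(data.X[test][:, cols])
        vote = _majority_vote(preds, scores, model.classes)
        folds.append(FoldResult(subject, sel, preds, scores, vote, None,
                                float("nan")))
        subj_pred.append(vote)

    subjects = data.subjects
    truth = np.array([data.subject_y(s) for s in subjects])
    predicted = np.array(subj_pred)
    n_correct = int((predicted == truth).sum())
    n = subjects.size
    return CVReport(folds=folds, subjects=subjects, truth=truth,
                    predicted=predicted, task="classification",
                    n_correct=n_correct, accuracy=n_correct / n,
                    p_value=binomial_tail(n_correct, n, 1.0 / K),
                    p_chance=1.0 / K)


def _select_top_t_multi(X, labels, k, classes) -> FeatureSelection:
    if classes.size == 2:
        return select_top_t(X, labels, k)
    from .filters import _top_k, _welch_t_cols
    best = np.zeros(X.shape[1])
    for a in range(classes.size):
        for b in range(a + 1, classes.size):
            t = np.abs(_welch_t_cols(X[labels == classes[a]],
                                     X[labels == classes[b]]))
            best = np.maximum(best, t)
    return FeatureSelection(_top_k(best, k), best, k)


def loocv_svr(data: GroupedDataset, k: int, C: float, epsilon: float,
              kernel: svm.KernelSpec | None = None) -> CVReport:
    """SVR LOOCV with a per-fold age-correlation filter."""
    kernel = kernel or svm.KernelSpec()
    if data.subjects.size < 3:
        raise EvaluationError("need at least 3 subjects")
    folds = []
    subj_pred = []
    for subject, train, test in _folds(data):
        ages = data.y[train].astype(float)
        if np.std(ages) == 0:
            raise EvaluationError(
                f"fold {subject}: training ages are constant")
        sel = select_top_corr(data.X[train], ages, k)
        cols = sel.selected - 1
        model = svm.train_svr(data.X[train][:, cols], ages, C, epsilon,
                              kernel)
        preds = svm.predict_svr(model, data.X[test][:, cols])
        folds.append(FoldResult(subject, sel, preds, preds,
                                float(preds.mean()), model.w, model.b))
        subj_pred.append(float(preds.mean()))

    subjects = data.subjects
    truth = np.array([data.subject_y(s) for s in subjects], dtype=float)
    predicted = np.array(subj_pred)
    slope, intercept, r2, resid = regression_line(predicted, truth)
    return CVReport(folds=folds, subjects=subjects, truth=truth,
                    predicted=predicted, task="regression", slope=slope,
                    intercept=intercept, r2=r2, residuals=resid)


# ---------------------------------------------------------------------------
# holdout tuning

@dataclass
class TuningGrid:
    """Metric surface over (k, C) or (k, epsilon) with its argmax cell."""

    k_values: np.ndarray
    other_values: np.ndarray
    other_name: str                 # "C" or "epsilon"
    metric: np.ndarray              # len(k) x len(other)
    metric_name: str
    secondary: np.ndarray | None    # R^2 surface for SVR grids
    best_k: int = 0
    best_other: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, k in enumerate(self.k_values):
            for b, o in enumerate(self.other_values):
                row = {"k": k, self.other_name: o,
                       self.metric_name: self.metric[a, b]}
                if self.secondary is not None:
                    row["r2"] = self.secondary[a, b]
                rows.append(row)
        return pd.DataFrame(rows)


def make_holdout(data: GroupedDataset, n_subjects: int, seed: int
                 ) -> GroupedDataset:
    """Random subject subset (without replacement) used for tuning."""
    rng = np.random.default_rng(seed)
    subjects = data.subjects
    if n_subjects > subjects.size:
        raise EvaluationError("holdout larger than the dataset")
    chosen = rng.choice(subjects, size=n_subjects, replace=False)
    mask = np.isin(data.subject_of, chosen)
    return GroupedDataset(data.X[mask], data.subject_of[mask], data.y[mask])


def grid_search_classifier(holdout: GroupedDataset, k_grid, C_grid,
                           kernel: svm.KernelSpec | None = None
                           ) -> TuningGrid:
    """Holdout LOOCV accuracy over (k, C); argmax ties prefer smaller k,
    then smaller C."""
    k_grid = np.asarray(list(k_grid), dtype=int)
    C_grid = np.asarray(list(C_grid), dtype=float)
    if k_grid.size == 0 or C_grid.size == 0:
        raise EvaluationError("empty tuning grid")
    acc = np.zeros((k_grid.size, C_grid.size))
    for a, k in enumerate(k_grid):
        for b, C in enumerate(C_grid):
            acc[a, b] = loocv_classify(holdout, int(k), float(C),
                                       kernel).accuracy
    a, b = _argmax_cell(acc)
    return TuningGrid(k_grid, C_grid, "C", acc, "accuracy", None,
                      best_k=int(k_grid[a]), best_other=float(C_grid[b]))


def grid_search_svr(holdout: GroupedDataset, k_grid, eps_grid, C: float,
                    kernel: svm.KernelSpec | None = None) -> TuningGrid:
    """Holdout LOOCV regression slope (ties: R^2, then smaller k) over
    (k, epsilon)."""
    k_grid = np.asarray(list(k_grid), dtype=int)
    eps_grid = np.asarray(list(eps_grid), dtype=float)
    if k_grid.size == 0 or eps_grid.size == 0:
        raise EvaluationError("empty tuning grid")
    slope = np.zeros((k_grid.size, eps_grid.size))
    r2 = np.zeros_like(slope)
    for a, k in enumerate(k_grid):
        for b, eps in enumerate(eps_grid):
            rep = loocv_svr(holdout, int(k), C, float(eps), kernel)
            slope[a, b] = rep.slope
            r2[a, b] = rep.r2
    a, b = _argmax_cell(slope, secondary=r2)
    return TuningGrid(k_grid, eps_grid, "epsilon", slope, "slope", r2,
                      best_k=int(k_grid[a]), best_other=float(eps_grid[b]))


def _argmax_cell(metric: np.ndarray, secondary: np.ndarray | None = None
                 ) -> tuple[int, int]:
    """Deterministic argmax: metric desc, then secondary desc, then smaller
    row (k) and column indices."""
    best = None
    for a in range(metric.shape[0]):
        for b in range(metric.shape[1]):
            key = (-metric[a, b],
                   -(secondary[a, b] if secondary is not None else 0.0),
                   a, b)
            if best is None or key < best[0]:
                best = (key, a, b)
    return best[1], best[2]
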