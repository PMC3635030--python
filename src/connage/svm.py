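"""Support-vector models trained by an exact dense QP solver.

Three model families, all sharing :mod:`connage.qp`:

* soft-margin binary SVM, trained in the dual
      max_a sum a_i - 1/2 sum_ij y_i y_j a_i a_j k(x_i, x_j)
      s.t.  sum y_i a_i = 0,  0 <= a_i <= C
* epsilon-insensitive SVR, trained in the dual over (a, a*)
* Weston-Watkins multiclass SVM (linear kernel), trained in the primal
      min 1/2 sum_m ||w_m||^2 + C sum_i sum_{m != y_i} xi_im
      s.t.  w_{y_i} x_i + b_{y_i} >= w_m x_i + b_m + 2 - xi_im,  xi >= 0
  with the gauge fixed by sum_m b_m = 0 (predictions and objective are
  invariant to a common shift of the biases).

Kernels: linear, and Gaussian RBF k(x, x') = exp(-||x - x'||^2 / (2 s^2))
with bandwidth s = 2 by default.  Linear models expose the explicit weight
vector w = sum y_i a_i x_i; RBF weights are deliberately not exposed because
they have no per-feature interpretation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .qp import solve_qp


class SVMError(ValueError):
    pass


DEFAULT_SIGMA = 2.0

# dual coefficients below this (times C) count as zero
_ALPHA_TOL = 1e-7


@dataclass
class KernelSpec:
    kind: str = "linear"
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise SVMError(f"unknown kernel {self.kind!r}")
        if self.kind == "rbf" and self.sigma <= 0:
            raise SVMError("rbf sigma must be positive")

    def matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(np.asarray(A, dtype=float))
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if A.shape[1] != B.shape[1]:
            raise SVMError(
                f"dimension mismatch: {A.shape[1]} vs {B.shape[1]} features")
        if self.kind == "linear":
            return A @ B.T
        d2 = cdist(A, B, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * self.sigma ** 2))


def _check_X(X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise SVMError("non-finite feature values")
    return X


# ---------------------------------------------------------------------------
# binary SVM

@dataclass
class BinarySVMModel:
    X: np.ndarray
    y: np.ndarray
    alpha: np.ndarray
    b: float
    C: float
    kernel: KernelSpec
    w: np.ndarray | None = None  # linear kernel only

    @property
    def support(self) -> np.ndarray:
        """Indices of training examples with alpha > 0."""
        return np.flatnonzero(self.alpha > _ALPHA_TOL * self.C)

    def dual_objective(self) -> float:
        K = self.kernel.matrix(self.X, self.X)
        ya = self.y * self.alpha
        return float(self.alpha.sum() - 0.5 * ya @ K @ ya)

    def to_dict(self) -> dict:
        return {
            "type": "binary_svm", "C": self.C,
            "kernel": {"kind": self.kernel.kind, "sigma": self.kernel.sigma},
            "alpha": self.alpha.tolist(), "b": self.b,
            "support": self.support.tolist(),
            "w": None if self.w is None else self.w.tolist(),
            "X": self.X.tolist(), "y": self.y.tolist(),
        }


def train_binary_svm(X, y, C: float, kernel: KernelSpec | None = None
                     ) -> BinarySVMModel:
    """Train a soft-margin SVM; labels must be in {-1, +1}."""
    X = _check_X(X)
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise SVMError("labels must contain both -1 and +1")
    if C <= 0:
        raise SVMError("C must be positive")
    kernel = kernel or KernelSpec()
    n = len(y)
    K = kernel.matrix(X, X)
    P = (np.outer(y, y)) * K
    q = -np.ones(n)
    G = np.vstack([np.eye(n), -np.eye(n)])
    h = np.concatenate([np.full(n, C), np.zeros(n)])
    res = solve_qp(P, q, G, h, A=y[None, :], b=np.zeros(1))
    alpha = np.clip(res.x, 0.0, C)

    g = K @ (y * alpha)  # decision values without bias
    b = _svm_bias(y, alpha, g, C)
    w = X.T @ (y * alpha) if kernel.kind == "linear" else None
    return BinarySVMModel(X=X, y=y, alpha=alpha, b=b, C=C, kernel=kernel,
                          w=w)


def _svm_bias(y, alpha, g, C) -> float:
    tol = max(_ALPHA_TOL * C, 1e-10)
    on_margin = (alpha > tol) & (alpha < C - tol)
    if on_margin.any():
        return float(np.mean(y[on_margin] - g[on_margin]))
    # no free support vectors: bias anywhere in the KKT-feasible interval;
    # take its midpoint
    lo, hi = -np.inf, np.inf
    # KKT: y_i (g_i + b) >= 1 where alpha=0, <= 1 where alpha=C
    for i in range(len(y)):
        if alpha[i] <= tol:
            if y[i] > 0:
                lo = max(lo, 1 - g[i])
            else:
                hi = min(hi, -1 - g[i])
        elif alpha[i] >= C - tol:
            if y[i] > 0:
                hi = min(hi, 1 - g[i])
            else:
                lo = max(lo, -1 - g[i])
    if np.isfinite(lo) and np.isfinite(hi):
        return float((lo + hi) / 2)
    if np.isfinite(lo):
        return float(lo)
    if np.isfinite(hi):
        return float(hi)
    return 0.0


def decision_function(model: BinarySVMModel, X) -> np.ndarray:
    """f(x) = sum_j y_j a_j k(x_j, x) + b (kernel expansion)."""
    X = _check_X(X)
    K = model.kernel.matrix(X, model.X)
    return K @ (model.y * model.alpha) + model.b


def classify(model: BinarySVMModel, X) -> np.ndarray:
    """sign of the decision value; exact zeros count as +1."""
    return np.where(decision_function(model, X) >= 0, 1.0, -1.0)


def extract_weights(model: BinarySVMModel) -> np.ndarray:
    """Explicit weight vector w = sum_i y_i a_i x_i (linear kernel only)."""
    if model.kernel.kind != "linear":
        raise SVMError(
            "RBF models have no per-feature weight vector; kernel weights "
            "are not interpretable as feature importances")
    return model.X.T @ (model.y * model.alpha)


# ---------------------------------------------------------------------------
# epsilon-insensitive SVR

@dataclass
class SVRModel:
    X: np.ndarray
    alpha: np.ndarray       # coefficients for y - f > epsilon side
    alpha_star: np.ndarray  # coefficients for f - y > epsilon side
    b: float
    C: float
    epsilon: float
    kernel: KernelSpec
    w: np.ndarray | None = None

    @property
    def beta(self) -> np.ndarray:
        """Net expansion coefficients a - a*."""
        return self.alpha - self.alpha_star

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.beta) > _ALPHA_TOL * self.C)

    def dual_objective(self, y: np.ndarray) -> float:
        K = self.kernel.matrix(self.X, self.X)
        beta = self.beta
        return float(y @ beta - self.epsilon * (self.alpha
                     + self.alpha_star).sum() - 0.5 * beta @ K @ beta)

    def to_dict(self) -> dict:
        return {
            "type": "svr", "C": self.C, "epsilon": self.epsilon,
            "kernel": {"kind": self.kernel.kind, "sigma": self.kernel.sigma},
            "alpha": self.alpha.tolist(),
            "alpha_star": self.alpha_star.tolist(), "b": self.b,
            "support": self.support.tolist(),
            "w": None if self.w is None else self.w.tolist(),
            "X": self.X.tolist(),
        }


def train_svr(X, y, C: float, epsilon: float,
              kernel: KernelSpec | None = None) -> SVRModel:
    """Train epsilon-insensitive support-vector regression.

    Points inside the epsilon tube around the fitted function carry no loss
    and end with both dual coefficients zero.
    """
    X = _check_X(X)
    y = np.asarray(y, dtype=float).ravel()
    if C <= 0:
        raise SVMError("C must be positive")
    if epsilon < 0:
        raise SVMError("epsilon must be non-negative")
    kernel = kernel or KernelSpec()
    n = len(y)
    K = kernel.matrix(X, X)
    P = np.block([[K, -K], [-K, K]])
    q = np.concatenate([epsilon - y, epsilon + y])
    eye = np.eye(2 * n)
    G = np.vstack([eye, -eye])
    h = np.concatenate([np.full(2 * n, C), np.zeros(2 * n)])
    Aeq = np.concatenate([np.ones(n), -np.ones(n)])[None, :]
    res = solve_qp(P, q, G, h, A=Aeq, b=np.zeros(1))
    a = np.clip(res.x[:n], 0.0, C)
    astar = np.clip(res.x[n:], 0.0, C)
    # complementarity a_i a*_i = 0 exactly: subtracting the common part
    # leaves a - a* unchanged and never increases the objective
    common = np.minimum(a, astar)
    a -= common
    astar -= common

    g = K @ (a - astar)
    b = _svr_bias(y, a, astar, g, C, epsilon)
    w = X.T @ (a - astar) if kernel.kind == "linear" else None
    return SVRModel(X=X, alpha=a, alpha_star=astar, b=b, C=C,
                    epsilon=epsilon, kernel=kernel, w=w)


def _svr_bias(y, a, astar, g, C, eps) -> float:
    tol = max(_ALPHA_TOL * C, 1e-10)
    free = (a > tol) & (a < C - tol)
    free_star = (astar > tol) & (astar < C - tol)
    cands = np.concatenate([(y - g - eps)[free], (y - g + eps)[free_star]])
    if cands.size:
        return float(cands.mean())
    lo, hi = -np.inf, np.inf
    for i in range(len(y)):
        if a[i] <= tol and astar[i] <= tol:
            lo = max(lo, y[i] - g[i] - eps)
            hi = min(hi, y[i] - g[i] + eps)
        elif a[i] >= C - tol:
            hi = min(hi, y[i] - g[i] - eps)
        elif astar[i] >= C - tol:
            lo = max(lo, y[i] - g[i] + eps)
    if np.isfinite(lo) and np.isfinite(hi):
        return float((lo + hi) / 2)
    return float(lo if np.isfinite(lo) else (hi if np.isfinite(hi) else 0.0))


def predict_svr(model: SVRModel, X) -> np.ndarray:
    X = _check_X(X)
    K = model.kernel.matrix(X, model.X)
    return K @ model.beta + model.b


# ---------------------------------------------------------------------------
# Weston-Watkins multiclass SVM

@dataclass
class MultiClassSVMModel:
    classes: np.ndarray       # sorted original labels, length K
    W: np.ndarray             # K x p per-class weight vectors
    biases: np.ndarray        # length K
    C: float
    objective: float = field(default=float("nan"))

    def scores(self, X) -> np.ndarray:
        X = _check_X(X)
        return X @ self.W.T + self.biases

    def predict(self, X) -> np.ndarray:
        # np.argmax takes the first maximum, i.e. the smallest class index
        return self.classes[np.argmax(self.scores(X), axis=1)]


def train_multiclass_svm(X, y, C: float) -> MultiClassSVMModel:
    """Weston-Watkins all-together multiclass SVM (linear kernel).

    Solves the single joint QP over all class weight vectors rather than
    a set of one-vs-rest problems.
    """
    X = _check_X(X)
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    K = classes.size
    if K < 2:
        raise SVMError("need at least 2 classes")
    if C <= 0:
        raise SVMError("C must be positive")
    n, p = X.shape
    yidx = np.searchsorted(classes, y)

    # variables: [w_1..w_K (p each) | b_1..b_K | xi (n*(K-1))]
    nw = K * p
    nxi = n * (K - 1)
    nv = nw + K + nxi
    P = np.zeros((nv, nv))
    P[:nw, :nw] = np.eye(nw)
    q = np.zeros(nv)
    q[nw + K:] = C

    rows = []
    h = []
    xi_col = 0
    for i in range(n):
        for m in range(K):
            if m == yidx[i]:
                continue
            row = np.zeros(nv)
            row[m * p:(m + 1) * p] = X[i]
            row[yidx[i] * p:(yidx[i] + 1) * p] = -X[i]
            row[nw + m] = 1.0
            row[nw + yidx[i]] = -1.0
            row[nw + K + xi_col] = -1.0
            rows.append(row)
            h.append(-2.0)
            xi_col += 1
    G_margin = np.array(rows)
    G_xi = np.zeros((nxi, nv))
    G_xi[:, nw + K:] = -np.eye(nxi)
    G = np.vstack([G_margin, G_xi])
    h = np.concatenate([np.array(h), np.zeros(nxi)])

    # gauge: common shift of the biases is a flat direction; pin sum b = 0
    A = np.zeros((1, nv))
    A[0, nw:nw + K] = 1.0
    res = solve_qp(P, q, G, h, A=A, b=np.zeros(1))
    W = res.x[:nw].reshape(K, p)
    biases = res.x[nw:nw + K]
    xi = np.maximum(res.x[nw + K:], 0.0)
    obj = 0.5 * np.sum(W ** 2) + C * xi.sum()
    return MultiClassSVMModel(classes=classes, W=W, biases=biases, C=C,
                              objective=float(obj))


def multiclass_objective(model: MultiClassSVMModel, X, y) -> float:
    """Primal WW objective recomputed from the model (slacks implied)."""
    X = _check_X(X)
    y = np.asarray(y).ravel()
    yidx = np.searchsorted(model.classes, y)
    S = model.scores(X)
    own = S[np.arange(len(y)), yidx]
    slack = np.maximum(0.0, 2.0 - (own[:, None] - S))
    slack[np.arange(len(y)), yidx] = 0.0
    return float(0.5 * np.sum(model.W ** 2) + model.C * slack.sum())


# ---------------------------------------------------------------------------
# serialization

def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    kernel = KernelSpec(**d["kernel"]) if "kernel" in d else None
    if d["type"] == "binary_svm":
        return BinarySVMModel(
            X=np.array(d["X"]), y=np.array(d["y"]),
            alpha=np.array(d["alpha"]), b=d["b"], C=d["C"], kernel=kernel,
            w=None if d["w"] is None else np.array(d["w"]))
    if d["type"] == "svr":
        return SVRModel(
            X=np.array(d["X"]), alpha=np.array(d["alpha"]),
            alpha_star=np.array(d["alpha_star"]), b=d["b"], C=d["C"],
            epsilon=d["epsilon"], kernel=kernel,
            w=None if d["w"] is None else np.array(d["w"]))
    raise SVMError(f"unknown model type {d.get('type')!r}")
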