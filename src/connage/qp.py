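"""Dense convex quadratic programming by a primal-dual interior-point method.

Solves

    minimize    (1/2) x' P x + q' x
    subject to  G x <= h,   A x = b

with P symmetric positive semidefinite.  This is the single solver behind
every support-vector training problem in :mod:`connage.svm` (binary dual,
epsilon-SVR dual, Weston-Watkins primal).  The implementation is a standard
Mehrotra predictor-corrector scheme with infeasible start; problem sizes in
this package are a few hundred variables, so dense linear algebra is used
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.linalg import LinAlgWarning


class QPError(RuntimeError):
    """Raised when the interior-point iteration fails to converge."""


@dataclass
class QPResult:
    x: np.ndarray
    obj: float
    iterations: int
    # duality gap and residual norms at termination, for diagnostics
    gap: float
    resid: float


def _solve_kkt(H: np.ndarray, A: np.ndarray | None, r1: np.ndarray,
               r2: np.ndarray | None) -> tuple[np.ndarray, np.ndarray | None]:
    """Solve [[H, A'], [A, 0]] [dx, dnu] = [r1, r2] (A may be absent)."""
    n = H.shape[0]
    if A is None or A.size == 0:
        return _chol_solve(H, r1), None
    p = A.shape[0]
    K = np.zeros((n + p, n + p))
    K[:n, :n] = H
    K[:n, n:] = A.T
    K[n:, :n] = A
    # tiny negative regularisation on the (2,2) block keeps K quasi-definite
    K[n:, n:] = -1e-12 * np.eye(p)
    rhs = np.concatenate([r1, r2])
    try:
        with warnings.catch_warnings():
            # near convergence the KKT system is intentionally ill
            # conditioned (complementarity products -> 0)
            warnings.simplefilter("ignore", LinAlgWarning)
            sol = scipy.linalg.solve(K, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError:
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    return sol[:n], sol[n:]


def _chol_solve(H: np.ndarray, r: np.ndarray) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(H, check_finite=False)
        return scipy.linalg.cho_solve((c, low), r, check_finite=False)
    except scipy.linalg.LinAlgError:
        return np.linalg.lstsq(H, r, rcond=None)[0]


def solve_qp(P, q, G, h, A=None, b=None, *, tol: float = 1e-9,
             max_iter: int = 100) -> QPResult:
    """Minimise ``0.5 x'Px + q'x`` subject to ``Gx <= h`` and ``Ax = b``.

    Parameters
    ----------
    P, q : quadratic and linear objective terms; P must be PSD (a small
        static regularisation is added internally for factorisation only).
    G, h : inequality constraints (required; box constraints included here).
    A, b : optional equality constraints.
    tol : relative tolerance on duality gap and residuals.

    Returns
    -------
    QPResult with the primal solution and objective value.
    """
    P = np.asarray(P, dtype=float)
    q = np.asarray(q, dtype=float).ravel()
    G = np.asarray(G, dtype=float)
    h = np.asarray(h, dtype=float).ravel()
    n = q.size
    m = h.size
    if A is not None:
        A = np.atleast_2d(np.asarray(A, dtype=float))
        b = np.atleast_1d(np.asarray(b, dtype=float))

    # static regularisation keeps the reduced KKT system factorisable when P
    # is singular (kernel matrices with duplicate points, WW slack block)
    reg = 1e-10 * (1.0 + np.trace(P) / max(n, 1))

    x = np.zeros(n)
    s = np.maximum(h - G @ x, 1.0)
    lam = np.ones(m)
    nu = np.zeros(A.shape[0]) if A is not None else None

    best: QPResult | None = None
    for it in range(max_iter):
        rd = P @ x + q + G.T @ lam
        if A is not None:
            rd = rd + A.T @ nu
            re = A @ x - b
        else:
            re = None
        rp = G @ x + s - h
        mu = s @ lam / m

        obj = 0.5 * x @ P @ x + q @ x
        # relative measures: the duality gap against the objective size,
        # each residual against the size of the terms entering it (so a
        # huge, slack C bound cannot mask poor convergence elsewhere)
        gap_scale = 1.0 + abs(obj)
        rd_scale = 1.0 + np.linalg.norm(q) + np.linalg.norm(G.T @ lam)
        rp_scale = 1.0 + np.linalg.norm(s)
        resid = (np.linalg.norm(rd) / rd_scale
                 + np.linalg.norm(rp) / rp_scale
                 + (np.linalg.norm(re) if re is not None else 0.0))
        if mu < tol * gap_scale and resid < tol * 100:
            return QPResult(x=x, obj=obj, iterations=it, gap=mu, resid=resid)
        if best is None or mu + resid < best.gap + best.resid:
            best = QPResult(x=x.copy(), obj=obj, iterations=it,
                            gap=mu, resid=resid)

        w = lam / s  # m-vector
        H = P + (G.T * w) @ G + reg * np.eye(n)

        def direction(rc):
            r1 = -(rd + G.T @ ((lam * rp - rc) / s))
            r2 = -re if re is not None else None
            dx, dnu = _solve_kkt(H, A, r1, r2)
            dlam = w * (G @ dx + rp) - rc / s
            ds = -(rc + s * dlam) / lam
            return dx, ds, dlam, dnu

        # affine (predictor) step
        rc_aff = lam * s
        dx_a, ds_a, dlam_a, dnu_a = direction(rc_aff)
        alpha_a = _step_length(s, ds_a, lam, dlam_a, 1.0)
        mu_aff = ((s + alpha_a * ds_a) @ (lam + alpha_a * dlam_a)) / m
        sigma = (mu_aff / mu) ** 3 if mu > 0 else 0.0

        # corrector step
        rc = lam * s - sigma * mu + ds_a * dlam_a
        dx, ds, dlam, dnu = direction(rc)
        alpha = _step_length(s, ds, lam, dlam, 0.99)

        x = x + alpha * dx
        s = s + alpha * ds
        lam = lam + alpha * dlam
        if nu is not None:
            nu = nu + alpha * dnu

    # accept a near-converged iterate rather than fail outright
    if best is not None and best.gap < 1e4 * tol and best.resid < 1e5 * tol:
        return best
    raise QPError(
        f"interior-point iteration did not converge in {max_iter} steps "
        f"(gap={best.gap if best else float('nan'):.3e})")


def _step_length(s, ds, lam, dlam, frac: float) -> float:
    """Largest step in (0, 1] keeping s and lam strictly positive."""
    alpha = 1.0
    neg = ds < 0
    if neg.any():
        alpha = min(alpha, frac * np.min(-s[neg] / ds[neg]))
    neg = dlam < 0
    if neg.any():
        alpha = min(alpha, frac * np.min(-lam[neg] / dlam[neg]))
    return max(alpha, 0.0)
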