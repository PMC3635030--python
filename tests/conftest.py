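"""Shared fixtures: study-scale synthetic cohorts and their LOOCV reports.

The recovery cohort reproduces the parameter-recovery study conditions:
30+30 subjects, 3 scans each, 100 ROIs, 50 informative edges planted at a
between-group Cohen's d of 1.5 (subject level), with the edge slope derived
in closed form from d.  Session-scoped so the expensive LOOCV runs once.
"""

from dataclasses import replace

import numpy as np
import pytest

import connage as ca
from connage.synthetic import (CohortSpec, GroupSpec,
                               edge_effect_for_cohens_d, three_group_spec,
                               young_old_spec)

RECOVERY_SEED = 11
SVR_SEED = 21


@pytest.fixture(scope="session")
def recovery_cohort():
    spec = CohortSpec(groups=[GroupSpec(30, 19, 35, "young"),
                              GroupSpec(30, 55, 85, "old")],
                      n_informative_edges=50, seed=RECOVERY_SEED)
    spec = replace(spec, edge_effect=edge_effect_for_cohens_d(spec, 1.5))
    return ca.generate_cohort(spec)


@pytest.fixture(scope="session")
def recovery_report(recovery_cohort):
    data = recovery_cohort.to_grouped_dataset("group")
    return ca.loocv_classify(data, k=100, C=0.1)


@pytest.fixture(scope="session")
def svr_cohort():
    beta = edge_effect_for_cohens_d(young_old_spec(), 1.5)
    spec = three_group_spec(n_informative_edges=50, edge_effect=beta,
                            seed=SVR_SEED)
    return ca.generate_cohort(spec)


@pytest.fixture(scope="session")
def svr_report(svr_cohort):
    data = svr_cohort.to_grouped_dataset("age")
    return ca.loocv_svr(data, k=298, C=1.0, epsilon=0.1)


@pytest.fixture()
def tiny_cohort():
    """Small, cheap cohort for structural tests: 8+8 subjects, 15 ROIs."""
    spec = CohortSpec(groups=[GroupSpec(8, 19, 35, "young"),
                              GroupSpec(8, 55, 85, "old")],
                      n_rois=15, n_informative_edges=10, edge_effect=0.5,
                      seed=5)
    return ca.generate_cohort(spec)


def ww_primal_objective_oracle(X, y, K, C):
    """Independent optimum of the Weston-Watkins primal.

    Same mathematical program as the trainer (explicit slacks, margin 2)
    but solved by scipy's trust-region constrained optimizer on explicit
    linear constraints.
    """
    import scipy.optimize as opt

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    nw, nxi = K * p, n * (K - 1)
    nv = nw + K + nxi

    def objective(v):
        return 0.5 * v[:nw] @ v[:nw] + C * v[nw + K:].sum()

    def jac(v):
        g = np.zeros(nv)
        g[:nw] = v[:nw]
        g[nw + K:] = C
        return g

    H = np.zeros((nv, nv))
    H[:nw, :nw] = np.eye(nw)

    rows = []
    col = 0
    for i in range(n):
        for m in range(K):
            if m == y[i]:
                continue
            row = np.zeros(nv)
            row[y[i] * p:(y[i] + 1) * p] = X[i]
            row[m * p:(m + 1) * p] = -X[i]
            row[nw + y[i]] += 1.0
            row[nw + m] -= 1.0
            row[nw + K + col] = 1.0
            rows.append(row)
            col += 1
    A = np.array(rows)
    lb = np.full(nv, -np.inf)
    lb[nw + K:] = 0.0
    res = opt.minimize(objective, np.zeros(nv), jac=jac, hess=lambda v: H,
                       method="trust-constr",
                       constraints=[opt.LinearConstraint(A, 2.0, np.inf)],
                       bounds=opt.Bounds(lb, np.full(nv, np.inf)),
                       options={"maxiter": 3000, "gtol": 1e-12,
                                "xtol": 1e-14})
    return res.fun


def permute_subject_labels(cohort, column, seed):
    """Return a GroupedDataset with the per-subject column permuted."""
    rng = np.random.default_rng(seed)
    subs = cohort.subjects.copy()
    subs[column] = rng.permutation(subs[column].to_numpy())
    per = subs.set_index("id")[column]
    y = per.loc[cohort.scans["subject_id"]].to_numpy()
    return ca.GroupedDataset(cohort.X,
                             cohort.scans["subject_id"].to_numpy(), y)
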