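"""Grouped LOOCV, exact binomial significance, tuning, regression metrics."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

import connage as ca
from connage.evaluation import (EvaluationError, GroupedDataset,
                                binomial_tail, grid_search_classifier,
                                grid_search_svr, loocv_classify,
                                loocv_multiclass, loocv_svr, make_holdout,
                                regression_line)
from connage.synthetic import CohortSpec, GroupSpec, generate_cohort

from conftest import permute_subject_labels


# ---------------------------------------------------------------------------
# binomial tail

def test_binomial_tail_boundary_values():
    assert binomial_tail(0, 10, 0.5) == pytest.approx(1.0)
    assert binomial_tail(1, 1, 0.5) == pytest.approx(0.5)


def test_binomial_tail_exact_summation_44_of_52():
    # oracle: exact integer arithmetic, frozen
    exact = float(Fraction(sum(comb(52, k) for k in range(44, 53)), 2 ** 52))
    assert exact == pytest.approx(2.0196608696565477e-07, rel=1e-12)
    assert binomial_tail(44, 52, 0.5) == pytest.approx(exact, rel=1e-9)
    # symmetry: upper tail at 44 equals lower tail at 8 for p = 1/2
    lower = float(Fraction(sum(comb(52, k) for k in range(0, 9)), 2 ** 52))
    assert binomial_tail(44, 52, 0.5) == pytest.approx(lower, rel=1e-9)


def test_binomial_tail_identities_and_monotonicity():
    n, p = 20, 0.3
    for k in range(1, n + 1):
        # tail(k) - tail(k+1) = pmf(k)
        upper_next = binomial_tail(k + 1, n, p) if k < n else 0.0
        assert binomial_tail(k, n, p) - upper_next == pytest.approx(
            stats.binom.pmf(k, n, p), abs=1e-12)
        assert binomial_tail(k, n, p) <= binomial_tail(k - 1, n, p) + 1e-15
    # complement identity: tail(k) + cdf(k-1) = 1
    assert binomial_tail(7, n, p) + stats.binom.cdf(6, n, p) == \
        pytest.approx(1.0, abs=1e-12)


def test_binomial_tail_rejects_bad_arguments():
    with pytest.raises(EvaluationError):
        binomial_tail(11, 10, 0.5)
    with pytest.raises(EvaluationError):
        binomial_tail(5, 10, 1.0)


# ---------------------------------------------------------------------------
# regression line

def test_regression_line_perfect_predictor():
    true = np.array([20.0, 40.0, 60.0, 80.0])
    slope, intercept, r2, resid = regression_line(true, true)
    assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))
    np.testing.assert_allclose(resid, 0.0, atol=1e-12)


def test_regression_line_half_slope_fit():
    true = np.linspace(19, 85, 9)
    predicted = 0.5 * true + 23.0
    slope, intercept, r2, _ = regression_line(predicted, true)
    assert slope == pytest.approx(0.5)
    assert intercept == pytest.approx(23.0)
    assert r2 == pytest.approx(1.0)


def test_regression_line_matches_normal_equations():
    rng = np.random.default_rng(0)
    true = rng.uniform(20, 80, 30)
    predicted = 0.4 * true + rng.normal(scale=8.0, size=30) + 25
    slope, intercept, r2, resid = regression_line(predicted, true)
    A = np.column_stack([true, np.ones(30)])
    coef = np.linalg.solve(A.T @ A, A.T @ predicted)
    assert slope == pytest.approx(coef[0], abs=1e-10)
    assert intercept == pytest.approx(coef[1], abs=1e-10)
    assert r2 == pytest.approx(np.corrcoef(predicted, true)[0, 1] ** 2)
    np.testing.assert_allclose(resid, predicted - A @ coef, atol=1e-10)


def test_regression_line_rejects_constant_truth():
    with pytest.raises(EvaluationError):
        regression_line([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# grouped dataset structure

def test_dataset_rejects_inconsistent_subjects():
    X = np.zeros((4, 3))
    with pytest.raises(EvaluationError, match="same number of scans"):
        GroupedDataset(X, ["a", "a", "a", "b"], [0, 0, 0, 1])
    with pytest.raises(EvaluationError, match="differs across scans"):
        GroupedDataset(X, ["a", "a", "b", "b"], [0, 1, 1, 1])


# ---------------------------------------------------------------------------
# binary LOOCV

def _noiseless_cohort(n_per_group=4, n_rois=10, seed=1):
    return generate_cohort(CohortSpec(
        groups=[GroupSpec(n_per_group, 19, 35, "young"),
                GroupSpec(n_per_group, 55, 85, "old")],
        n_rois=n_rois, n_informative_edges=5, edge_effect=1.0,
        subject_sd=0.0, scan_sd=0.0, seed=seed))


def test_noiseless_cohort_classified_perfectly():
    data = _noiseless_cohort().to_grouped_dataset("group")
    report = loocv_classify(data, k=10, C=1.0)
    assert report.accuracy == 1.0
    assert report.p_value == pytest.approx(0.5 ** 8)


def test_accuracy_equals_recomputed_fold_correctness(recovery_report,
                                                     recovery_cohort):
    truth = recovery_cohort.subjects.set_index("id")["group"]
    correct = [fold.subject_pred == truth.loc[fold.held_out_subject]
               for fold in recovery_report.folds]
    assert recovery_report.accuracy == pytest.approx(np.mean(correct))
    assert recovery_report.n_correct == sum(correct)


def test_permuted_labels_give_chance_level_accuracy():
    """Label permutation breaks the planted signal: accuracy falls inside
    the exact binomial 99% band around 1/2."""
    spec = CohortSpec(groups=[GroupSpec(15, 19, 35, "young"),
                              GroupSpec(15, 55, 85, "old")],
                      n_rois=30, n_informative_edges=20, edge_effect=0.3,
                      seed=14)
    cohort = generate_cohort(spec)
    n = 30
    half_width = 2.576 * np.sqrt(0.25 / n)
    for perm_seed in range(5):
        data = permute_subject_labels(cohort, "group", 100 + perm_seed)
        report = loocv_classify(data, k=30, C=0.1)
        assert abs(report.accuracy - 0.5) <= half_width + 1e-12


def test_training_fold_never_sees_held_out_scans(tiny_cohort):
    """Twinning guard: scribbling over one subject's scans changes nothing
    about the model trained when that subject is held out."""
    data = tiny_cohort.to_grouped_dataset("group")
    target = data.subjects[3]
    report1 = loocv_classify(data, k=15, C=0.5)

    X2 = data.X.copy()
    X2[data.subject_of == target] = 123.456
    data2 = GroupedDataset(X2, data.subject_of, data.y)
    report2 = loocv_classify(data2, k=15, C=0.5)

    f1 = next(f for f in report1.folds if f.held_out_subject == target)
    f2 = next(f for f in report2.folds if f.held_out_subject == target)
    np.testing.assert_array_equal(f1.selection.selected,
                                  f2.selection.selected)
    np.testing.assert_allclose(f1.w, f2.w, atol=1e-9)
    assert f1.b == pytest.approx(f2.b, abs=1e-9)


def test_loocv_is_deterministic(tiny_cohort):
    data = tiny_cohort.to_grouped_dataset("group")
    r1 = loocv_classify(data, k=10, C=0.5)
    r2 = loocv_classify(data, k=10, C=0.5)
    assert r1.to_dict() == r2.to_dict()


# ---------------------------------------------------------------------------
# multiclass LOOCV

def _three_group_separable(seed=2):
    return generate_cohort(CohortSpec(
        groups=[GroupSpec(4, 20, 25, "a"), GroupSpec(4, 45, 50, "b"),
                GroupSpec(4, 70, 75, "c")],
        n_rois=10, n_informative_edges=8, edge_effect=1.0,
        subject_sd=0.0, scan_sd=0.01, seed=seed))


def test_separated_three_groups_classified_perfectly():
    data = _three_group_separable().to_grouped_dataset("group")
    report = loocv_multiclass(data, k=10, C=10.0)
    assert report.accuracy == 1.0
    assert report.p_chance == pytest.approx(1.0 / 3.0)


def test_multiclass_permuted_labels_near_chance():
    cohort = generate_cohort(CohortSpec(
        groups=[GroupSpec(7, 20, 30, "a"), GroupSpec(7, 45, 55, "b"),
                GroupSpec(7, 70, 80, "c")],
        n_rois=15, n_informative_edges=10, edge_effect=0.3, seed=3))
    data = permute_subject_labels(cohort, "group", 200)
    report = loocv_multiclass(data, k=15, C=0.1)
    # 99% binomial band around 1/3 with n = 21
    half_width = 2.576 * np.sqrt((1 / 3) * (2 / 3) / 21)
    assert abs(report.accuracy - 1 / 3) <= half_width + 1e-12


def test_two_class_multiclass_agrees_with_binary(tiny_cohort):
    data = tiny_cohort.to_grouped_dataset("group")
    binary = loocv_classify(data, k=12, C=1.0)
    multi = loocv_multiclass(data, k=12, C=1.0)
    np.testing.assert_array_equal(binary.predicted, multi.predicted)


# ---------------------------------------------------------------------------
# SVR LOOCV

def test_noiseless_linear_age_cohort_r2_near_one():
    cohort = generate_cohort(CohortSpec(
        groups=[GroupSpec(12, 19, 85, "all")], n_rois=10,
        n_informative_edges=5, edge_effect=1.0, subject_sd=0.0,
        scan_sd=0.0, seed=4))
    data = cohort.to_grouped_dataset("age")
    report = loocv_svr(data, k=5, C=100.0, epsilon=0.01)
    assert report.r2 > 0.99
    assert report.slope == pytest.approx(1.0, abs=0.05)


def test_permuted_ages_destroy_svr_performance(svr_cohort):
    data = permute_subject_labels(svr_cohort, "age", 5)
    report = loocv_svr(data, k=298, C=1.0, epsilon=0.1)
    assert report.r2 < 0.1


def test_svr_twinning_guard(tiny_cohort):
    data = tiny_cohort.to_grouped_dataset("age")
    target = data.subjects[0]
    r1 = loocv_svr(data, k=10, C=1.0, epsilon=0.1)
    X2 = data.X.copy()
    X2[data.subject_of == target] = -7.0
    r2 = loocv_svr(GroupedDataset(X2, data.subject_of, data.y),
                   k=10, C=1.0, epsilon=0.1)
    f1 = next(f for f in r1.folds if f.held_out_subject == target)
    f2 = next(f for f in r2.folds if f.held_out_subject == target)
    np.testing.assert_array_equal(f1.selection.selected,
                                  f2.selection.selected)
    np.testing.assert_allclose(f1.w, f2.w, atol=1e-8)


def test_svr_requires_nonconstant_ages():
    cohort = generate_cohort(CohortSpec(
        groups=[GroupSpec(4, 50, 50, "g")], n_rois=6,
        n_informative_edges=0, seed=6))
    data = cohort.to_grouped_dataset("age")
    with pytest.raises(EvaluationError, match="constant"):
        loocv_svr(data, k=5, C=1.0, epsilon=0.1)


# ---------------------------------------------------------------------------
# holdout tuning

def test_make_holdout_subset_and_determinism(tiny_cohort):
    data = tiny_cohort.to_grouped_dataset("group")
    h1 = make_holdout(data, 6, seed=9)
    h2 = make_holdout(data, 6, seed=9)
    assert set(h1.subjects) <= set(data.subjects)
    assert h1.subjects.size == 6
    np.testing.assert_array_equal(h1.subjects, h2.subjects)
    with pytest.raises(EvaluationError):
        make_holdout(data, 100, seed=0)


def test_single_cell_grid_is_argmax(tiny_cohort):
    data = tiny_cohort.to_grouped_dataset("group")
    grid = grid_search_classifier(data, [10], [0.5])
    assert grid.best_k == 10 and grid.best_other == 0.5
    assert grid.metric.shape == (1, 1)


def test_grid_tie_break_prefers_smaller_k_then_smaller_C():
    data = _noiseless_cohort(n_per_group=3).to_grouped_dataset("group")
    # separable at every cell: all accuracies 1.0, ties everywhere
    grid = grid_search_classifier(data, [5, 10], [0.1, 1.0])
    assert np.all(grid.metric == 1.0)
    assert grid.best_k == 5 and grid.best_other == 0.1


def test_svr_grid_reports_slope_and_r2(tiny_cohort):
    data = tiny_cohort.to_grouped_dataset("age")
    grid = grid_search_svr(data, [5, 10], [0.1], C=1.0)
    assert grid.metric.shape == (2, 1)
    assert grid.secondary is not None
    frame = grid.to_frame()
    assert set(frame.columns) == {"k", "epsilon", "slope", "r2"}
    # argmax cell carries the maximal slope
    assert grid.metric.max() == pytest.approx(
        grid.metric[list(grid.k_values).index(grid.best_k),
                    list(grid.other_values).index(grid.best_other)])
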