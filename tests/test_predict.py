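"""Design assembly, splits, baselines, boosted search, metric suite."""

import numpy as np
import pandas as pd
import pytest

from mstraj.cohort import Cohort, DomainError, PatientRecord, series_from_pairs
from mstraj.descriptors import compute_all
from mstraj.predict import (
    DEFAULT_XGB_PARAMS,
    Design,
    LEAKAGE_COLUMNS,
    _cv_loss,
    build_design,
    fit_baseline,
    fit_boosted,
    macro_ovr_auc,
    make_split,
)
from mstraj.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="module")
def small_cohort():
    cohort, _ = generate_cohort(SynthConfig(n_patients=250, seed=21))
    return cohort


@pytest.fixture(scope="module")
def small_desc(small_cohort):
    return compute_all(small_cohort)


class TestBuildDesign:
    def test_regression_rows_match_cohort(self, small_cohort, small_desc):
        d = build_design(small_cohort, small_desc, "beta1")
        assert len(d.y) == len(small_cohort)
        assert d.kind == "regression"

    def test_rare_classes_dropped_with_rows(self, small_cohort, small_desc):
        d = build_design(small_cohort, small_desc, "edss_1")
        pooled = small_desc["edss_1"].dropna().astype(float).map(
            lambda v: ">=6" if v >= 6 else f"{v:g}")
        counts = pooled.value_counts()
        expected_kept = counts[counts >= 10]
        assert sorted(d.class_names) == sorted(expected_kept.index)
        assert len(d.y) == int(expected_kept.sum())
        assert d.dropped_classes == {str(k): int(v)
                                     for k, v in counts[counts < 10].items()}

    def test_six_and_above_pooled(self, small_cohort, small_desc):
        d = build_design(small_cohort, small_desc, "edss_10")
        assert not any(c in d.class_names for c in ("6", "6.5", "7", "8"))
        assert ">=6" in d.class_names

    def test_no_leakage_columns(self, small_cohort, small_desc):
        d = build_design(small_cohort, small_desc, "edss_5")
        assert not set(d.X.columns) & LEAKAGE_COLUMNS

    def test_under_two_classes_domain_error(self):
        patients = tuple(
            PatientRecord(f"p{i}", "female", 30.0, {},
                          series_from_pairs([(0, 2.0), (400, 2.0)]))
            for i in range(15)
        )
        cohort = Cohort(patients)
        desc = compute_all(cohort)
        with pytest.raises(DomainError):
            build_design(cohort, desc, "edss_1")


class TestSplits:
    def test_deterministic_and_disjoint(self, small_cohort, small_desc):
        d = build_design(small_cohort, small_desc, "edss_2")
        s1, s2 = make_split(d, 3), make_split(d, 3)
        assert np.array_equal(s1.train_idx, s2.train_idx)
        assert np.array_equal(s1.test_idx, s2.test_idx)
        assert set(s1.train_idx).isdisjoint(s1.test_idx)
        s3 = make_split(d, 4)
        assert not np.array_equal(np.sort(s1.test_idx), np.sort(s3.test_idx))

    def test_folds_partition_train(self, small_cohort, small_desc):
        d = build_design(small_cohort, small_desc, "edss_2")
        sp = make_split(d, 0)
        val_union = np.concatenate([v for _, v in sp.folds])
        assert sorted(val_union) == sorted(sp.train_idx)

    def test_stratification_within_one_sample(self, small_cohort, small_desc):
        d = build_design(small_cohort, small_desc, "edss_2")
        sp = make_split(d, 0)
        y = d.y.to_numpy()
        train_counts = pd.Series(y[sp.train_idx]).value_counts()
        for _, val_idx in sp.folds:
            val_counts = pd.Series(y[val_idx]).value_counts()
            for cls, total in train_counts.items():
                ideal = total * len(val_idx) / len(sp.train_idx)
                assert abs(val_counts.get(cls, 0) - ideal) <= 1.0


class TestBaselines:
    def test_noiseless_linear_target_recovered(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = pd.Series(X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.7)
        d = Design(X=X, y=y, kind="regression", target="beta1",
                   patient_ids=[str(i) for i in range(80)])
        sp = make_split(d, 0)
        rep = fit_baseline(d, sp)
        assert rep.test_metrics["mae"] < 1e-8

    def test_separable_two_class_perfect(self):
        X = pd.DataFrame({"f": np.r_[np.zeros(30), np.ones(30)]})
        y = pd.Series(np.r_[np.zeros(30, int), np.ones(30, int)])
        d = Design(X=X, y=y, kind="classification", target="edss_1",
                   patient_ids=[str(i) for i in range(60)], class_names=["a", "b"])
        sp = make_split(d, 0)
        rep = fit_baseline(d, sp)
        assert rep.test_metrics["accuracy"] == 1.0

    def test_permuted_target_no_better_than_intercept(self, small_cohort, small_desc):
        d = build_design(small_cohort, small_desc, "beta2")
        rng = np.random.default_rng(5)
        d_perm = Design(X=d.X, y=pd.Series(rng.permutation(d.y.to_numpy())),
                        kind="regression", target="beta2", patient_ids=d.patient_ids)
        sp = make_split(d_perm, 0)
        rep = fit_baseline(d_perm, sp)
        cv_mae = np.mean([m["mae"] for m in rep.cv_metrics])
        intercept_mae = np.mean([
            np.abs(d_perm.y.iloc[v] - d_perm.y.iloc[f].mean()).mean()
            for f, v in sp.folds])
        assert cv_mae >= intercept_mae * 0.95


class TestMetrics:
    def test_macro_auc_hand_example(self):
        proba = np.array([[0.1, 0.9], [0.2, 0.8], [0.7, 0.3], [0.8, 0.2]])
        y = np.array([1, 1, 0, 0])
        assert macro_ovr_auc(y, proba, [0, 1]) == 1.0

    def test_absent_class_excluded_from_macro(self):
        proba = np.array([[0.6, 0.2, 0.2], [0.1, 0.8, 0.1], [0.7, 0.2, 0.1]])
        y = np.array([0, 1, 0])  # class 2 absent
        val = macro_ovr_auc(y, proba, [0, 1, 2])
        assert np.isfinite(val)

    def test_bounded_prediction_error_bounds_mae(self):
        y = pd.Series(np.linspace(0, 1, 40))
        X = pd.DataFrame({"x": y})
        d = Design(X=X, y=y, kind="regression", target="beta1",
                   patient_ids=[str(i) for i in range(40)])
        sp = make_split(d, 1)
        rep = fit_baseline(d, sp)  # exact linear fit
        assert rep.test_metrics["mae"] <= 1e-9


@pytest.fixture(scope="module")
def design_split(small_cohort, small_desc):
    d = build_design(small_cohort, small_desc, "beta1")
    return d, make_split(d, 2)


class TestBoosted:

    def test_budget_one_equals_default(self, design_split):
        d, sp = design_split
        default_rep, tuned_rep = fit_boosted(d, sp, budget=1, seed=2)
        assert tuned_rep.hyperparameters == DEFAULT_XGB_PARAMS
        assert tuned_rep.test_metrics == default_rep.test_metrics

    def test_search_never_worse_than_default(self, design_split):
        d, sp = design_split
        _, tuned_rep = fit_boosted(d, sp, budget=6, seed=2)
        default_loss = _cv_loss(d, sp, DEFAULT_XGB_PARAMS)
        tuned_loss = _cv_loss(d, sp, tuned_rep.hyperparameters)
        assert tuned_loss <= default_loss + 1e-12

    def test_seeded_search_deterministic(self, design_split):
        d, sp = design_split
        _, t1 = fit_boosted(d, sp, budget=5, seed=3)
        _, t2 = fit_boosted(d, sp, budget=5, seed=3)
        assert t1.hyperparameters == t2.hyperparameters
        assert t1.test_metrics == t2.test_metrics

    def test_overfit_gap_reported(self, design_split):
        d, sp = design_split
        default_rep, _ = fit_boosted(d, sp, budget=1, seed=0)
        assert set(default_rep.overfit_gap) == set(default_rep.train_metrics)
        assert isinstance(default_rep.flag_overfit(threshold=1e9), list)


def test_run_experiment_bundle_bookkeeping(small_cohort):
    """Full pipeline bundle: every feasible task appears with all three
    model reports, infeasible tasks are recorded as errors, and the
    binary course evaluation plus the three report tables are present."""
    from mstraj.predict import ALL_TARGETS, ExperimentConfig, run_experiment

    bundle = run_experiment(small_cohort, ExperimentConfig(seed=1, budget=1))
    assert set(bundle.reports) | set(bundle.errors) >= set(ALL_TARGETS)
    for target, reps in bundle.reports.items():
        assert set(reps) == {"multinomial_logistic", "xgboost_default",
                             "xgboost_tuned"} or \
            set(reps) == {"linear_regression", "xgboost_default", "xgboost_tuned"}
    assert bundle.binary_course is not None
    assert set(bundle.binary_course) == {"auc_roc", "sensitivity",
                                         "accuracy", "precision"}
    assert len(bundle.regression_table()) == 3
    assert not bundle.classification_table("test").empty
    assert not bundle.binary_course_table().empty


def test_shuffled_test_features_leave_train_metrics_unchanged(small_cohort, small_desc):
    d = build_design(small_cohort, small_desc, "beta1")
    sp = make_split(d, 0)
    rep = fit_baseline(d, sp)
    X_shuffled = d.X.copy()
    rng = np.random.default_rng(0)
    X_shuffled.iloc[sp.test_idx] = rng.permutation(
        X_shuffled.iloc[sp.test_idx].to_numpy())
    d2 = Design(X=X_shuffled, y=d.y, kind=d.kind, target=d.target,
                patient_ids=d.patient_ids)
    rep2 = fit_baseline(d2, sp)
    assert rep.train_metrics == rep2.train_metrics
    assert rep.test_metrics != rep2.test_metrics
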