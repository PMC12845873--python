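"""Fold construction, LASSO selection oracle, tuning, metrics, CV leakage."""

import numpy as np
import pandas as pd
import pytest

from eegfuse.modeling import (
    CVConfig,
    evaluate,
    fit_predict_logistic,
    lasso_select,
    run_cv,
    subject_kfold,
    tune_logistic_tpe,
)
from eegfuse.types import FeatureMatrix


def _orthonormal_design(rng, m=40, p=6):
    """Zero-mean orthonormal columns (so the LASSO solution is closed-form)."""
    raw = rng.standard_normal((m, p))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    return q[:, :p]


class TestSubjectKFold:
    def test_partition_contract(self):
        ids = [f"s{i}" for i in range(20)]
        y = ["A"] * 10 + ["B"] * 10
        folds = subject_kfold(ids, y, k=10, seed=0)
        assert sorted(np.bincount(folds).tolist()) == [2] * 10

    def test_each_subject_one_fold(self):
        ids = [f"s{i}" for i in range(15)]
        y = ["A"] * 8 + ["B"] * 7
        folds = subject_kfold(ids, y, k=5, seed=1)
        assert folds.size == 15 and set(folds) == set(range(5))

    def test_stratification(self):
        ids = [f"s{i}" for i in range(20)]
        y = np.array(["A"] * 10 + ["B"] * 10)
        folds = subject_kfold(ids, y, k=10, seed=2)
        for f in range(10):
            fold_labels = y[folds == f]
            assert sorted(fold_labels.tolist()) == ["A", "B"]

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            subject_kfold(["a", "b"], [0, 1], k=3)


class TestLassoSelect:
    def test_soft_threshold_oracle(self, rng):
        X = _orthonormal_design(rng)
        y = rng.integers(0, 2, size=X.shape[0]).astype(float)
        lam = 0.3
        res = lasso_select(X, y, lambda_grid=np.array([lam]), seed=0)
        beta = X.T @ y  # OLS coefficients under orthonormal design
        expected = np.sign(beta) * np.maximum(np.abs(beta) - lam / 2.0, 0.0)
        assert np.allclose(res.weights, expected, atol=1e-6)

    def test_full_shrinkage_fallback(self, rng):
        X = _orthonormal_design(rng)
        y = rng.integers(0, 2, size=X.shape[0]).astype(float)
        res = lasso_select(X, y, lambda_grid=np.array([1e6]), seed=0)
        assert res.fallback_used
        assert len(res.selected) == 1

    def test_unpenalized_limit_matches_ols(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.integers(0, 2, size=50).astype(float)
        res = lasso_select(X, y, lambda_grid=np.array([0.0]), seed=0)
        Xc = np.column_stack([X, np.ones(50)])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0][:4]
        assert np.allclose(res.weights, beta, atol=1e-6)

    def test_constant_column_dropped(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 0.0
        y = rng.integers(0, 2, size=30).astype(float)
        res = lasso_select(
            pd.DataFrame(X, columns=["a", "b", "c"]), y,
            lambda_grid=np.array([1e-4]), seed=0,
        )
        assert "b" not in res.selected

    def test_multiclass_union_support(self, rng):
        # three classes, each driven by its own feature
        n = 60
        y = np.repeat([0.0, 1.0, 2.0], n // 3)
        X = rng.standard_normal((n, 5)) * 0.1
        for c in range(3):
            X[y == c, c] += 3.0
        res = lasso_select(X, y, seed=0)
        assert {"x0", "x1", "x2"} <= set(res.selected)


class TestTune:
    def test_budget_one_returns_single_point(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([0, 1] * 10)
        out = tune_logistic_tpe(X, y, budget=1, seed=0)
        assert len(out["trials"]) == 1
        assert out["C"] == out["trials"][0]["C"]

    def test_argmax_contract(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 2, 30)
        out = tune_logistic_tpe(X, y, budget=8, seed=1)
        assert all(out["objective"] >= t["objective"] - 1e-12
                   for t in out["trials"])

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 2, 30)
        a = tune_logistic_tpe(X, y, budget=5, seed=3)
        b = tune_logistic_tpe(X, y, budget=5, seed=3)
        assert a["C"] == b["C"] and a["objective"] == b["objective"]

    def test_empty_search_space_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_logistic_tpe(rng.standard_normal((10, 2)),
                              np.array([0, 1] * 5), search_space={})


class TestFitPredict:
    def test_separable_perfect_accuracy(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)) + 5,
                       rng.standard_normal((20, 2)) - 5])
        y = np.array([1] * 20 + [0] * 20)
        proba, pred, _ = fit_predict_logistic(X, y, X, {"C": 1.0})
        assert np.mean(pred == y) == 1.0

    def test_probability_rows_sum_to_one(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 3, 30)
        proba, _, _ = fit_predict_logistic(X, y, X, {"C": 1.0})
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_training_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            fit_predict_logistic(X, np.zeros(10), X, {"C": 1.0})


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        m, cm = evaluate(y, proba, [0, 1])
        assert m == {"AUC": 1.0, "ACC": 1.0, "SPE": 1.0, "SEN": 1.0}
        assert np.array_equal(cm, [[2, 0], [0, 2]])

    def test_hand_computed_contingency(self):
        # TP=3 FP=1 TN=5 FN=1 (positive class = 1)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred_pos = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        proba = np.column_stack([1.0 - pred_pos, pred_pos]).astype(float)
        m, cm = evaluate(y, proba, [0, 1], positive_class=1)
        assert m["SEN"] == pytest.approx(0.75)
        assert m["SPE"] == pytest.approx(5 / 6, abs=1e-4)
        assert m["ACC"] == pytest.approx(0.8)
        assert cm.sum() == 10

    def test_random_scores_chance_auc(self, rng):
        n = 4000
        y = rng.integers(0, 2, n)
        p1 = rng.uniform(size=n)
        m, _ = evaluate(y, np.column_stack([1 - p1, p1]), [0, 1])
        se = np.sqrt(1 / 12 * (1 / np.sum(y == 1) + 1 / np.sum(y == 0)))
        assert abs(m["AUC"] - 0.5) <= 3 * se

    def test_three_class_macro_metrics(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        proba = np.eye(3)[[0, 0, 1, 2, 2, 2]].astype(float)
        m, cm = evaluate(y, proba, [0, 1, 2])
        assert m["ACC"] == pytest.approx(5 / 6)
        # per-class recall: 1, 0.5, 1 -> macro SEN
        assert m["SEN"] == pytest.approx((1 + 0.5 + 1) / 3)
        assert cm.shape == (3, 3) and cm.sum() == 6


def _feature_matrix(rng, n_per=10, p=8, delta=3.0):
    X = rng.standard_normal((2 * n_per, p))
    X[n_per:, 0] += delta
    ids = [f"s{i}" for i in range(2 * n_per)]
    y = ["HC"] * n_per + ["SCZ"] * n_per
    return FeatureMatrix(
        X=pd.DataFrame(X, index=ids, columns=[f"f{i+1}" for i in range(p)]),
        y=pd.Series(y, index=ids),
        mode="microstate",
    )


class TestRunCV:
    def test_no_leakage_and_train_only_statistics(self, rng):
        fm = _feature_matrix(rng)
        cv = run_cv(fm, CVConfig(k=5, n_repeats=2, seed=0, budget=3))
        for r in cv.fold_records:
            train, test = set(r["train_subjects"]), set(r["test_subjects"])
            assert not (train & test)
            mu = fm.X.loc[sorted(train)].to_numpy().mean(axis=0)
            assert np.allclose(mu, r["scaler_mean"], atol=1e-12)

    def test_separable_cohort_high_auc(self, rng):
        fm = _feature_matrix(rng, delta=4.0)
        cv = run_cv(fm, CVConfig(k=5, n_repeats=1, seed=1, budget=3))
        assert cv.summary["AUC"]["mean"] >= 0.9

    def test_permuted_labels_chance_accuracy(self, rng):
        fm = _feature_matrix(rng, delta=0.0)  # labels carry no signal
        cv = run_cv(fm, CVConfig(k=5, n_repeats=2, seed=2, budget=3))
        n = 20
        band = 1.96 * np.sqrt(0.25 / n)
        assert abs(cv.summary["ACC"]["mean"] - 0.5) <= band + 0.05

    def test_three_class_cv_runs(self, rng):
        n_per, p = 8, 6
        X = rng.standard_normal((3 * n_per, p))
        for c in range(3):
            X[c * n_per:(c + 1) * n_per, c] += 3.0
        ids = [f"s{i}" for i in range(3 * n_per)]
        y = ["HC"] * n_per + ["MILD"] * n_per + ["SEVERE"] * n_per
        fm = FeatureMatrix(
            X=pd.DataFrame(X, index=ids, columns=[f"f{i+1}" for i in range(p)]),
            y=pd.Series(y, index=ids), mode="fused",
        )
        cv = run_cv(fm, CVConfig(k=4, n_repeats=1, seed=3, budget=3))
        assert cv.confusion.sum() == 24
        assert cv.summary["ACC"]["mean"] > 0.7

    def test_determinism(self, rng):
        fm = _feature_matrix(rng)
        a = run_cv(fm, CVConfig(k=5, n_repeats=1, seed=4, budget=3))
        b = run_cv(fm, CVConfig(k=5, n_repeats=1, seed=4, budget=3))
        assert a.summary == b.summary
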