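"""Subject-wise cross-validated classification.

Per outer fold: z-score standardization fitted on the training subjects,
L1 (LASSO) feature selection on the training subjects with the
regularization strength chosen by inner CV, a logistic-regression
classifier whose inverse regularization C is tuned by seeded random
search over a log-uniform range, and AUC / ACC / SPE / SEN evaluation on
the held-out subjects.  Nothing fitted ever sees a test subject.

The LASSO objective follows the squared-loss form

    min_w  sum_i (y_i - w.x_i)^2 + lambda * ||w||_1

with numerically encoded labels; multi-class problems run one-vs-rest
selections and take the union of the nonzero supports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, LinearRegression, LogisticRegression
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from ._seeds import derive_seed
from .types import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.logspace(-4, 1, 30)
METRIC_NAMES = ("AUC", "ACC", "SPE", "SEN")


@dataclass
class SelectionResult:
    lam: float
    weights: np.ndarray  # (n_features,) or (n_classes, n_features)
    selected: list[str]
    fallback_used: bool = False


@dataclass
class CVConfig:
    k: int = 10
    n_repeats: int = 10
    seed: int = 0
    budget: int = 20
    lambda_grid: np.ndarray | None = None
    c_range: tuple[float, float] = (1e-3, 1e3)
    positive_class: object | None = None
    collect_explanations: bool = False


@dataclass
class CVResult:
    classes: list
    fold_records: list[dict] = field(default_factory=list)
    summary: dict[str, dict[str, float]] = field(default_factory=dict)
    confusion: np.ndarray | None = None
    fold_assignments: list[dict] = field(default_factory=list)
    selected_counts: pd.Series | None = None
    explanation: object | None = None


def subject_kfold(
    subject_ids: Sequence[str],
    labels: Sequence,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Label-stratified, subject-disjoint fold assignment (one per subject)."""
    subject_ids = list(subject_ids)
    if k > len(subject_ids):
        raise ValueError(f"k={k} exceeds number of subjects ({len(subject_ids)})")
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(subject_ids), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = f
    return folds


def _lasso_path_select(
    X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray, seed: int
) -> tuple[float, np.ndarray]:
    """Pick lambda by inner 3-fold CV (MSE), return (lambda, weights)."""
    m = X.shape[0]
    alphas = np.asarray(lambda_grid, dtype=float) / (2.0 * m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if alphas.size == 1:
            lam = float(lambda_grid[0])
            if lam == 0.0:
                model = LinearRegression().fit(X, y)
                return lam, model.coef_.copy()
            model = Lasso(alpha=alphas[0], max_iter=50000).fit(X, y)
            return lam, model.coef_.copy()
        cv = KFold(n_splits=min(3, m), shuffle=True, random_state=seed)
        model = LassoCV(alphas=np.sort(alphas)[::-1], cv=cv, max_iter=50000)
        model.fit(X, y)
    lam = float(model.alpha_ * 2.0 * m)
    return lam, model.coef_.copy()


def lasso_select(
    X_train: pd.DataFrame | np.ndarray,
    y_train: Sequence,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> SelectionResult:
    """L1-penalized squared-loss feature selection.

    ``X_train`` must already be standardized with training statistics.
    Constant columns are dropped with a warning.  Multi-class labels run
    one-vs-rest selections; the selected set is the union of nonzero
    supports.  If everything shrinks to zero, the single largest-|weight|
    feature at the smallest grid lambda is returned with a flag.
    """
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    if isinstance(X_train, pd.DataFrame):
        names = list(X_train.columns)
        X = X_train.to_numpy(dtype=float)
    else:
        X = np.asarray(X_train, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]

    keep = X.std(axis=0) > 0
    if not keep.all():
        logger.warning("dropping %d constant feature columns", (~keep).sum())
    kept_idx = np.flatnonzero(keep)
    Xk = X[:, keep]

    classes = np.unique(np.asarray(y_train))
    if classes.size < 2:
        raise ValueError("y_train must contain at least 2 classes")
    if classes.size == 2:
        codes = (np.asarray(y_train) == classes[1]).astype(float)
        targets = [codes]
    else:
        targets = [
            (np.asarray(y_train) == c).astype(float) for c in classes
        ]

    lam_used = 0.0
    weight_rows = []
    for t in targets:
        lam, w = _lasso_path_select(Xk, t, np.asarray(lambda_grid), seed)
        lam_used = lam
        weight_rows.append(w)
    W = np.vstack(weight_rows)

    full = np.zeros((W.shape[0], X.shape[1]))
    full[:, kept_idx] = W
    support = np.flatnonzero(np.any(full != 0, axis=0))
    fallback = False
    if support.size == 0:
        fallback = True
        lam_min = float(np.min(lambda_grid))
        refit_rows = []
        for t in targets:
            _, w = _lasso_path_select(
                Xk, t, np.array([max(lam_min, 1e-8)]), seed
            )
            refit_rows.append(w)
        Wr = np.vstack(refit_rows)
        best = kept_idx[int(np.argmax(np.abs(Wr).max(axis=0)))]
        support = np.array([best])
        logger.warning(
            "LASSO shrank all weights to zero; falling back to feature %s",
            names[best],
        )
    weights = full[0] if classes.size == 2 else full
    return SelectionResult(
        lam=lam_used,
        weights=weights,
        selected=[names[i] for i in support],
        fallback_used=fallback,
    )


def tune_logistic_tpe(
    X_train: np.ndarray,
    y_train: Sequence,
    search_space: dict | None = None,
    budget: int = 50,
    seed: int = 0,
) -> dict:
    """Seeded random search over log-uniform C, scored by inner 3-fold CV.

    A sequential model-free stand-in for Tree-structured-Parzen-Estimator
    tuning: candidates are drawn log-uniformly from the search range and
    the best mean inner-CV accuracy wins (first encountered on ties).
    Deterministic for a given seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if search_space is None:
        search_space = {"C": (1e-3, 1e3)}
    if not search_space:
        raise ValueError("empty search space")
    lo, hi = search_space["C"]
    rng = np.random.default_rng(seed)
    candidates = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=budget)

    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    n_splits = min(3, np.min(np.unique(y, return_counts=True)[1]))
    trials = []
    best: dict | None = None
    for c in candidates:
        if n_splits >= 2:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            accs = []
            for tr, te in cv.split(X, y):
                clf = LogisticRegression(C=c, max_iter=2000)
                clf.fit(X[tr], y[tr])
                accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
            score = float(np.mean(accs))
        else:  # degenerate tiny folds: score on training accuracy
            clf = LogisticRegression(C=c, max_iter=2000)
            clf.fit(X, y)
            score = float(np.mean(clf.predict(X) == y))
        trials.append({"C": float(c), "objective": score})
        if best is None or score > best["objective"]:
            best = {"C": float(c), "objective": score}
    assert best is not None
    best["trials"] = trials
    return best


def fit_predict_logistic(
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, LogisticRegression]:
    """Fit (multinomial) logistic regression, return probabilities + labels."""
    c = float(params.get("C", 1.0)) if params else 1.0
    if len(np.unique(np.asarray(y_train))) < 2:
        raise ValueError("training fold contains a single class")
    clf = LogisticRegression(C=c, max_iter=5000)
    clf.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    proba = clf.predict_proba(np.asarray(X_test, dtype=float))
    pred = clf.classes_[np.argmax(proba, axis=1)]
    return proba, pred, clf


def evaluate(
    y_true: Sequence,
    probabilities: np.ndarray,
    classes: Sequence,
    positive_class: object | None = None,
) -> tuple[dict[str, float], np.ndarray]:
    """AUC / ACC / SPE / SEN and the confusion matrix (rows = true class).

    Binary: standard definitions with the patient group as positive class
    (sensitivity = patient detection).  Three or more classes: overall
    accuracy, macro one-vs-rest AUC, macro specificity and sensitivity.
    Classes absent from ``y_true`` are excluded from the macro averages
    with a warning.
    """
    y = np.asarray(y_true)
    proba = np.asarray(probabilities, dtype=float)
    classes = list(classes)
    if proba.shape != (y.size, len(classes)):
        raise ValueError("probabilities shape does not match y/classes")
    pred = np.asarray(classes)[np.argmax(proba, axis=1)]
    cm = sk_confusion(y, pred, labels=classes)
    acc = float(np.mean(pred == y))

    present = [c for c in classes if np.any(y == c)]
    if len(present) < len(classes):
        logger.warning(
            "classes absent from y_true excluded from macro metrics: %s",
            sorted(set(map(str, classes)) - set(map(str, present))),
        )

    def ovr_terms(c) -> tuple[float, float, float]:
        i = classes.index(c)
        is_pos = y == c
        tp = float(np.sum(is_pos & (pred == c)))
        fn = float(np.sum(is_pos & (pred != c)))
        tn = float(np.sum(~is_pos & (pred != c)))
        fp = float(np.sum(~is_pos & (pred == c)))
        sen = tp / (tp + fn) if tp + fn else np.nan
        spe = tn / (tn + fp) if tn + fp else np.nan
        if is_pos.all() or (~is_pos).all():
            auc = np.nan
        else:
            auc = float(roc_auc_score(is_pos, proba[:, i]))
        return auc, spe, sen

    if len(classes) == 2:
        pos = positive_class if positive_class is not None else classes[-1]
        auc, spe, sen = ovr_terms(pos)
    else:
        terms = np.array([ovr_terms(c) for c in present])
        auc, spe, sen = (float(np.nanmean(terms[:, j])) for j in range(3))
    return {"AUC": auc, "ACC": acc, "SPE": spe, "SEN": sen}, cm


def run_cv(fm: FeatureMatrix, config: CVConfig | None = None) -> CVResult:
    """Repeated subject-wise k-fold CV with in-fold selection and tuning.

    Standardization statistics, the LASSO support, and the tuned C are all
    derived from training subjects only; metrics are averaged over every
    fold of every repeat, with 95% CIs from the normal approximation
    mean +/- 1.96 * SD / sqrt(n_folds).
    """
    cfg = config or CVConfig()
    classes = sorted(pd.unique(fm.y), key=str)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    subjects = np.array(fm.subject_ids)
    Xall = fm.X.to_numpy(dtype=float)
    yall = fm.y.to_numpy()
    names = list(fm.X.columns)

    result = CVResult(classes=classes)
    pooled_cm = np.zeros((len(classes), len(classes)), dtype=int)
    selected_counter: dict[str, int] = {}
    exp_chunks: list[dict] = []

    for rep in range(cfg.n_repeats):
        rep_seed = derive_seed(cfg.seed, f"repeat{rep}")
        folds = subject_kfold(subjects, yall, k=cfg.k, seed=rep_seed)
        result.fold_assignments.append(dict(zip(subjects, folds.tolist())))
        for f in range(cfg.k):
            test_mask = folds == f
            train_mask = ~test_mask
            Xtr, ytr = Xall[train_mask], yall[train_mask]
            Xte, yte = Xall[test_mask], yall[test_mask]

            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd_safe = np.where(sd > 0, sd, 1.0)
            Xtr_s = (Xtr - mu) / sd_safe
            Xte_s = (Xte - mu) / sd_safe

            fold_seed = derive_seed(rep_seed, f"fold{f}")
            y_codes = np.array([classes.index(v) for v in ytr], dtype=float)
            sel = lasso_select(
                pd.DataFrame(Xtr_s, columns=names),
                y_codes,
                lambda_grid=cfg.lambda_grid,
                seed=fold_seed,
            )
            cols = [names.index(n) for n in sel.selected]
            params = tune_logistic_tpe(
                Xtr_s[:, cols], ytr, {"C": cfg.c_range},
                budget=cfg.budget, seed=fold_seed,
            )
            proba, _pred, model = fit_predict_logistic(
                Xtr_s[:, cols], ytr, Xte_s[:, cols], params
            )
            # align probability columns to the global class order
            proba_full = np.zeros((proba.shape[0], len(classes)))
            for j, c in enumerate(model.classes_):
                proba_full[:, classes.index(c)] = proba[:, j]
            metrics, cm = evaluate(
                yte, proba_full, classes, positive_class=cfg.positive_class
            )
            pooled_cm += cm
            for n in sel.selected:
                selected_counter[n] = selected_counter.get(n, 0) + 1
            result.fold_records.append(
                {
                    "repeat": rep,
                    "fold": f,
                    "train_subjects": subjects[train_mask].tolist(),
                    "test_subjects": subjects[test_mask].tolist(),
                    "selected": list(sel.selected),
                    "lambda": sel.lam,
                    "C": params["C"],
                    "metrics": metrics,
                    "scaler_mean": mu,
                    "scaler_std": sd_safe,
                }
            )
            if cfg.collect_explanations:
                from .explain import linear_shap

                exp = linear_shap(
                    model,
                    pd.DataFrame(Xte_s[:, cols],
                                 columns=[names[i] for i in cols],
                                 index=subjects[test_mask]),
                    background_mean=np.zeros(len(cols)),
                )
                exp_chunks.append(
                    {"explanation": exp, "columns": cols,
                     "sample_ids": subjects[test_mask].tolist(),
                     "model_classes": list(model.classes_)}
                )

    for m in METRIC_NAMES:
        vals = np.array([r["metrics"][m] for r in result.fold_records])
        mean = float(np.nanmean(vals))
        n = int(np.sum(~np.isnan(vals)))
        sd_m = float(np.nanstd(vals, ddof=1)) if n > 1 else 0.0
        half = 1.96 * sd_m / np.sqrt(n) if n else np.nan
        result.summary[m] = {
            "mean": mean, "ci_low": mean - half, "ci_high": mean + half,
        }
    result.confusion = pooled_cm
    result.selected_counts = pd.Series(selected_counter).sort_values(
        ascending=False
    )
    if cfg.collect_explanations and exp_chunks:
        from .explain import pool_fold_explanations

        result.explanation = pool_fold_explanations(exp_chunks, names, classes)
    return result
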