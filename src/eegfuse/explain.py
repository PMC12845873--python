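"""Exact Shapley attributions for the fitted logistic model.

For a linear model with independent features, the Shapley value of
feature i for one sample is w_i * (x_i - mu_i) on the margin (log-odds)
scale, with base value equal to the margin at the background mean.  The
closed form is exact, so local accuracy (base + sum of attributions =
model margin) holds to machine precision; no sampling approximation is
involved.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_F_NAME = re.compile(r"^f(\d+)$")
N_MICROSTATE = 24


@dataclass
class Explanation:
    """Per-class, per-sample, per-feature attributions on the margin scale.

    ``values`` has shape (n_classes, n_samples, n_features); ``base`` has
    shape (n_classes, n_samples) so that explanations pooled across CV
    folds (whose base values differ) remain locally accurate per sample.
    """

    class_labels: list
    feature_names: list[str]
    base: np.ndarray
    values: np.ndarray
    sample_ids: list | None = None

    @property
    def margins(self) -> np.ndarray:
        """Reconstructed model margins: base + sum of attributions."""
        return self.base + self.values.sum(axis=2)


def _coef_margins(model) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-class weight matrix and intercepts from a sklearn linear model."""
    coef = np.asarray(model.coef_, dtype=float)
    intercept = np.atleast_1d(np.asarray(model.intercept_, dtype=float))
    classes = list(getattr(model, "classes_", range(max(2, coef.shape[0]))))
    if coef.shape[0] == 1:  # binary: symmetric +/- margins for both classes
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])
    return coef, intercept, classes


def linear_shap(
    model,
    X: pd.DataFrame | np.ndarray,
    background_mean: np.ndarray,
    feature_names: list[str] | None = None,
) -> Explanation:
    """Exact linear Shapley values per class for every sample in ``X``."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        sample_ids = list(X.index)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = feature_names or [f"x{i}" for i in range(Xv.shape[1])]
        sample_ids = None
    model_names = getattr(model, "feature_names_in_", None)
    if model_names is not None and list(model_names) != names:
        raise ValueError("feature names do not match the fitted model")
    mu = np.asarray(background_mean, dtype=float)
    if mu.shape != (Xv.shape[1],):
        raise ValueError("background_mean length does not match features")

    coef, intercept, classes = _coef_margins(model)
    values = coef[:, None, :] * (Xv - mu)[None, :, :]
    base_scalar = coef @ mu + intercept  # (n_classes,)
    base = np.repeat(base_scalar[:, None], Xv.shape[0], axis=1)
    return Explanation(
        class_labels=classes,
        feature_names=names,
        base=base,
        values=values,
        sample_ids=sample_ids,
    )


def pool_fold_explanations(
    chunks: list[dict], all_names: list[str], classes: list
) -> Explanation:
    """Stitch per-fold explanations (selected-feature subsets) together.

    Unselected features receive zero attribution in their fold, which is
    exact: a feature the fold's model never saw has coefficient zero.
    """
    n_features = len(all_names)
    vals, bases, ids = [], [], []
    for ch in chunks:
        exp: Explanation = ch["explanation"]
        n_s = exp.values.shape[1]
        wide = np.zeros((len(classes), n_s, n_features))
        base = np.zeros((len(classes), n_s))
        for j, c in enumerate(exp.class_labels):
            gi = classes.index(c)
            wide[gi, :, ch["columns"]] = exp.values[j].T
            base[gi] = exp.base[j]
        vals.append(wide)
        bases.append(base)
        ids.extend(ch["sample_ids"])
    return Explanation(
        class_labels=list(classes),
        feature_names=list(all_names),
        base=np.concatenate(bases, axis=1),
        values=np.concatenate(vals, axis=1),
        sample_ids=ids,
    )


def global_importance(exp: Explanation, class_index: int) -> pd.DataFrame:
    """Features ranked by mean |attribution| for one class.

    Ties break by ascending feature index (position in the name list).
    """
    if exp.values.size == 0:
        raise ValueError("empty explanation")
    imp = np.abs(exp.values[class_index]).mean(axis=0)
    order = np.lexsort((np.arange(imp.size), -imp))
    df = pd.DataFrame(
        {
            "feature": [exp.feature_names[i] for i in order],
            "importance": imp[order],
        }
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def report_modality_contribution(exp: Explanation) -> dict:
    """Per-class share of mean |attribution| carried by each feature family.

    Features f1-f24 are the microstate family; f25 and beyond are EMD
    features.  Shares are normalized to sum to 1 per class.
    """
    idx = []
    for name in exp.feature_names:
        m = _F_NAME.match(name)
        if m is None:
            raise ValueError(
                f"feature name {name!r} does not follow the f-numbering"
            )
        idx.append(int(m.group(1)))
    idx = np.asarray(idx)
    is_ms = idx <= N_MICROSTATE
    out = {}
    for j, c in enumerate(exp.class_labels):
        imp = np.abs(exp.values[j]).mean(axis=0)
        ms = float(imp[is_ms].sum())
        em = float(imp[~is_ms].sum())
        total = ms + em
        if total == 0:
            out[c] = {"microstate": np.nan, "emd": np.nan}
        else:
            out[c] = {"microstate": ms / total, "emd": em / total}
    return out


def plot_importance(exp: Explanation, class_index: int, top: int = 20, ax=None):
    """Horizontal bar chart of the top global importances (optional)."""
    import matplotlib.pyplot as plt

    df = global_importance(exp, class_index).head(top)[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * top + 1))
    ax.barh(df["feature"], df["importance"])
    ax.set_xlabel("mean |Shapley value| (margin scale)")
    ax.set_title(f"class {exp.class_labels[class_index]}")
    return ax
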