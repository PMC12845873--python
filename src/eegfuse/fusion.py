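"""Feature-level fusion of microstate and EMD feature families.

The EMD tensor (channels x IMFs x statistics) is averaged over the IMF
axis without disturbing channel/statistic positions, then flattened
channel-major and concatenated after the 24 microstate parameters:

    R = [ W (24) | E_avg flattened (N x C) ]

giving 24 + 17 x 14 = 262 features for the default montage.  Fused
feature names follow the f-numbering convention: f1-f24 are microstate
features, f25 onward are EMD features.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ChannelStatMatrix,
    EMDFeatureTensor,
    FeatureMatrix,
    FusedFeatureVector,
    MicrostateFeatures,
)

logger = logging.getLogger(__name__)

MODES = ("microstate", "emd", "fused")


def average_over_imfs(t: EMDFeatureTensor) -> ChannelStatMatrix:
    """Mean over the IMF axis: N x M x C -> N x C."""
    return ChannelStatMatrix(
        values=t.values.mean(axis=1),
        channel_names=list(t.channel_names),
        statistic_names=list(t.statistic_names),
        subject_id=t.subject_id,
    )


def fused_feature_names(
    channel_names: Sequence[str], statistic_names: Sequence[str]
) -> list[str]:
    """f1..f24 then f25..f(24 + N*C)."""
    n_emd = len(channel_names) * len(statistic_names)
    return [f"f{i}" for i in range(1, 25 + n_emd)]


def emd_feature_names(
    channel_names: Sequence[str],
    statistic_names: Sequence[str],
    imf_index: Sequence[int] | None = None,
) -> list[str]:
    """Descriptive names for EMD-only feature vectors (channel-major)."""
    if imf_index is None:
        return [
            f"emd_{ch}_{st}" for ch in channel_names for st in statistic_names
        ]
    return [
        f"emd_{ch}_imf{j}_{st}"
        for ch in channel_names
        for j in imf_index
        for st in statistic_names
    ]


def fuse(w: MicrostateFeatures, e: ChannelStatMatrix) -> FusedFeatureVector:
    """Concatenate [24 microstate | channel-major averaged EMD]."""
    if (
        w.subject_id is not None
        and e.subject_id is not None
        and w.subject_id != e.subject_id
    ):
        raise ValueError(
            f"subject mismatch: microstate={w.subject_id} emd={e.subject_id}"
        )
    values = np.concatenate([w.to_vector(), np.asarray(e.values).reshape(-1)])
    names = fused_feature_names(e.channel_names, e.statistic_names)
    return FusedFeatureVector(
        values=values,
        names=names,
        subject_id=w.subject_id or e.subject_id or "",
        group_label="",
    )


def build_feature_matrix(
    subjects: Sequence[tuple[str, str | int, MicrostateFeatures | None,
                             EMDFeatureTensor | None]],
    mode: str,
) -> FeatureMatrix:
    """Stack per-subject features into a design matrix.

    ``subjects`` is an ordered list of (subject_id, group_label,
    microstate features, EMD tensor); the components a mode does not use
    may be None.  Row order equals input order.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rows, ids, labels = [], [], []
    columns: list[str] | None = None
    for sid, grp, w, t in subjects:
        if mode == "microstate":
            if w is None:
                raise ValueError(f"{sid}: microstate features missing")
            vec = w.to_vector()
            names = MicrostateFeatures.names()
        elif mode == "emd":
            if t is None:
                raise ValueError(f"{sid}: EMD tensor missing")
            vec = t.values.reshape(-1)
            names = emd_feature_names(
                t.channel_names, t.statistic_names, t.imf_index
            )
        else:
            if w is None or t is None:
                raise ValueError(f"{sid}: fused mode needs both families")
            fv = fuse(w, average_over_imfs(t))
            vec, names = fv.values, fv.names
        if columns is None:
            columns = names
        elif columns != names:
            raise ValueError(f"{sid}: heterogeneous feature columns")
        rows.append(vec)
        ids.append(sid)
        labels.append(grp)
    X = pd.DataFrame(np.vstack(rows), index=ids, columns=columns)
    X.index.name = "subject_id"
    y = pd.Series(labels, index=X.index, name="group_label")
    return FeatureMatrix(X=X, y=y, mode=mode)


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Persist as the interchange table: subject_id, group_label, features."""
    out = fm.X.copy()
    out.insert(0, "group_label", fm.y)
    out.to_csv(path)


def read_feature_matrix(path, mode: str = "fused") -> FeatureMatrix:
    df = pd.read_csv(path, index_col="subject_id")
    y = df.pop("group_label")
    return FeatureMatrix(X=df, y=y, mode=mode)
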