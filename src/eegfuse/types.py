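"""Shared container types for the feature-fusion pipeline.

All containers are thin dataclasses around numpy arrays / pandas frames;
every downstream stage consumes only these, never raw files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """One subject's multichannel EEG.

    ``data`` is channels x samples in microvolts; row order matches
    ``channel_names``.
    """

    subject_id: str
    group_label: str | int
    channel_names: list[str]
    sampling_rate: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic subject."""

    state_sequence: np.ndarray  # per-sample class index, 0..K-1
    templates: np.ndarray  # K x n_channels generating topographies
    duration_mean_ms: np.ndarray  # per-class requested mean segment duration
    transition_matrix: np.ndarray  # K x K row-stochastic, zero diagonal

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=int)
        self.templates = np.asarray(self.templates, dtype=float)


@dataclass
class GFPSeries:
    """Global field power: per-sample std of potentials across electrodes."""

    values: np.ndarray
    sampling_rate: float


@dataclass
class TemplateSet:
    """Microstate topographic templates (zero-mean, unit-norm rows)."""

    maps: np.ndarray  # K x n_channels
    labels: list[str]
    channel_names: list[str]
    gev: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class Segmentation:
    """Per-sample microstate class labels plus the derived segment list."""

    labels: np.ndarray
    sampling_rate: float
    segments: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.segments:
            self.segments = segments_from_labels(self.labels)


def segments_from_labels(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a label sequence into (start, end_exclusive, class)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


@dataclass
class MicrostateFeatures:
    """The 24 per-subject microstate parameters.

    Ordering of the flat vector (names f1..f24): mean duration A-D,
    occurrence A-D, coverage A-D, then the 12 ordered transition
    probabilities in row-major order A->B, A->C, A->D, B->A, ..., D->C.
    """

    mean_duration_ms: np.ndarray  # (4,)
    occurrence_per_s: np.ndarray  # (4,)
    coverage_fraction: np.ndarray  # (4,)
    transition_prob: np.ndarray  # (12,) row-major off-diagonal
    subject_id: str | None = None

    CLASS_LABELS = ("A", "B", "C", "D")

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.mean_duration_ms,
                self.occurrence_per_s,
                self.coverage_fraction,
                self.transition_prob,
            ]
        )

    @staticmethod
    def names() -> list[str]:
        return [f"f{i}" for i in range(1, 25)]

    @staticmethod
    def descriptive_names() -> list[str]:
        c = MicrostateFeatures.CLASS_LABELS
        out = [f"duration_{x}" for x in c]
        out += [f"occurrence_{x}" for x in c]
        out += [f"coverage_{x}" for x in c]
        out += [f"p_{a}to{b}" for a in c for b in c if a != b]
        return out


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions (highest frequency first) + residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_channel: str | None = None

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


@dataclass
class EMDFeatureTensor:
    """channels x IMFs x statistics feature block (N x M x C)."""

    values: np.ndarray
    channel_names: list[str]
    imf_index: list[int]
    statistic_names: list[str]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (
            len(self.channel_names),
            len(self.imf_index),
            len(self.statistic_names),
        ):
            raise ValueError("tensor shape inconsistent with axis labels")

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)


@dataclass
class ChannelStatMatrix:
    """EMD tensor averaged over the IMF axis: channels x statistics."""

    values: np.ndarray
    channel_names: list[str]
    statistic_names: list[str]
    subject_id: str | None = None


@dataclass
class FusedFeatureVector:
    """[24 microstate | channel-major flattened averaged-EMD] feature vector."""

    values: np.ndarray
    names: list[str]
    subject_id: str
    group_label: str | int


@dataclass
class FeatureMatrix:
    """Per-subject design matrix with labels; the modeling-stage input."""

    X: pd.DataFrame  # index = subject_id, columns = feature names
    y: pd.Series  # group labels aligned to X.index
    mode: str = "fused"

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share the subject index")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.X.index)
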