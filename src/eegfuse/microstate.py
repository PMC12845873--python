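"""EEG microstate analysis.

Global field power (GFP), GFP-peak topography sampling, polarity-invariant
(modified) K-means clustering into the four canonical classes A-D,
per-sample backfitting, and the 24 microstate parameters (mean duration,
occurrence, coverage per class, plus the 12 ordered transition
probabilities).

Microstate maps are sign-ambiguous (the dipolar topography flips polarity
with the oscillatory carrier), so every correlation here is squared /
absolute: plain Euclidean K-means would split each class into a +/- pair.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    GFPSeries,
    MicrostateFeatures,
    Recording,
    Segmentation,
    TemplateSet,
    segments_from_labels,
)

logger = logging.getLogger(__name__)

#: Approximate 2-D 10-20 electrode positions (x: left-/right+, y: post-/ant+)
#: used only to build the canonical A-D reference maps for labeling.
CHANNEL_POSITIONS = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.55, 0.48), "Fz": (0.0, 0.50),
    "F4": (0.55, 0.48), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.55, -0.48), "Pz": (0.0, -0.50),
    "P4": (0.55, -0.48), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

CLASS_LABELS = ["A", "B", "C", "D"]


def gfp(rec: Recording) -> GFPSeries:
    """Per-sample population standard deviation across electrodes."""
    if rec.n_channels < 2:
        raise ValueError("GFP requires at least 2 channels")
    values = rec.data.std(axis=0, ddof=0)
    return GFPSeries(values=values, sampling_rate=rec.sampling_rate)


def find_gfp_peaks(g: GFPSeries) -> np.ndarray:
    """Indices of strict local maxima of the GFP series (endpoints excluded)."""
    v = np.asarray(g.values)
    if v.size < 3:
        return np.array([], dtype=int)
    inner = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return np.flatnonzero(inner) + 1


def sample_peak_maps(
    rec: Recording,
    peaks: np.ndarray,
    n_maps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Uniformly sample (without replacement) peak topographies, zero-meaned.

    If fewer than ``n_maps`` peaks exist, all are used with a warning.
    Returns an array of shape (n_selected, n_channels).
    """
    peaks = np.asarray(peaks, dtype=int)
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    if peaks.size == 0:
        raise ValueError("no GFP peaks available to sample from")
    rng = np.random.default_rng(seed)
    take = min(n_maps, peaks.size)
    if take < n_maps:
        logger.warning(
            "%s: only %d GFP peaks available (requested %d)",
            rec.subject_id, peaks.size, n_maps,
        )
    chosen = rng.choice(peaks, size=take, replace=False)
    maps = rec.data[:, chosen].T.copy()
    maps -= maps.mean(axis=1, keepdims=True)
    return maps


def gev_score(
    maps: np.ndarray, templates: np.ndarray, assignments: np.ndarray
) -> float:
    """Global explained variance of an assignment.

    With zero-mean maps and zero-mean unit-norm templates this equals
    sum_i (x_i . t_a(i))^2 / sum_i ||x_i||^2, i.e. the GFP^2-weighted mean
    squared spatial correlation.
    """
    maps = np.asarray(maps, dtype=float)
    proj = np.einsum("ij,ij->i", maps, templates[assignments])
    denom = float(np.sum(maps**2))
    if denom == 0:
        return 0.0
    return float(np.sum(proj**2) / denom)


def _principal_map(cluster_maps: np.ndarray) -> np.ndarray:
    """First principal component of a set of maps (zero-mean, unit norm)."""
    cov = cluster_maps.T @ cluster_maps
    vals, vecs = np.linalg.eigh(cov)
    t = vecs[:, -1]
    t = t - t.mean()
    n = np.linalg.norm(t)
    if n == 0:  # degenerate: all maps flat
        t = np.zeros_like(t)
        t[0] = 1.0
        t -= t.mean()
        n = np.linalg.norm(t)
    return t / n


def cluster_microstates(
    maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    channel_names: list[str] | None = None,
    return_details: bool = False,
) -> TemplateSet | tuple[TemplateSet, dict]:
    """Polarity-invariant modified K-means over pooled GFP-peak maps.

    Assignment maximizes the squared spatial correlation (sign ignored);
    each template is re-estimated as the first principal component of its
    assigned maps, which monotonically increases the GEV within a restart.
    The best of ``n_restarts`` seeded restarts by GEV is returned.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("maps must be 2-D (n_maps x n_channels)")
    n_maps, n_ch = maps.shape
    if k > n_maps:
        raise ValueError(f"k={k} exceeds number of maps ({n_maps})")
    maps = maps - maps.mean(axis=1, keepdims=True)
    denom = float(np.sum(maps**2))

    rng = np.random.default_rng(seed)
    best: dict | None = None
    restart_gevs = []
    for _ in range(n_restarts):
        init_idx = rng.choice(n_maps, size=k, replace=False)
        templates = maps[init_idx].copy()
        norms = np.linalg.norm(templates, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        templates /= norms
        assignments = np.full(n_maps, -1)
        gev_history = []
        for _it in range(max_iter):
            proj = maps @ templates.T
            new_assign = np.argmax(proj**2, axis=1)
            new_templates = np.empty_like(templates)
            for c in range(k):
                members = maps[new_assign == c]
                if len(members) == 0:
                    new_templates[c] = maps[rng.integers(n_maps)]
                    nn = np.linalg.norm(new_templates[c])
                    new_templates[c] /= nn if nn else 1.0
                else:
                    new_templates[c] = _principal_map(members)
            gev_history.append(gev_score(maps, new_templates, new_assign))
            moved = 1.0 - np.abs(
                np.einsum("ij,ij->i", new_templates, templates)
            )
            converged = (
                np.array_equal(new_assign, assignments) or moved.max() < tol
            )
            assignments, templates = new_assign, new_templates
            if converged:
                break
        g = gev_score(maps, templates, assignments)
        restart_gevs.append(g)
        if best is None or g > best["gev"]:
            best = {
                "gev": g,
                "templates": templates,
                "assignments": assignments,
                "gev_history": gev_history,
            }
    assert best is not None
    names = channel_names or [f"ch{i + 1}" for i in range(n_ch)]
    ts = TemplateSet(
        maps=best["templates"],
        labels=[str(i + 1) for i in range(k)],
        channel_names=names,
        gev=best["gev"],
    )
    if return_details:
        best["restart_gevs"] = restart_gevs
        return ts, best
    return ts


def canonical_reference_maps(channel_names: list[str]) -> np.ndarray | None:
    """Canonical A-D reference topographies on a 10-20 channel set.

    A: left-posterior / right-anterior diagonal gradient; B: the mirrored
    diagonal; C: anterior-posterior gradient; D: fronto-central radial
    maximum.  Returns None when any channel lacks a tabulated position.
    """
    if any(ch not in CHANNEL_POSITIONS for ch in channel_names):
        return None
    xy = np.array([CHANNEL_POSITIONS[ch] for ch in channel_names])
    x, y = xy[:, 0], xy[:, 1]
    refs = np.stack(
        [
            (x + y) / np.sqrt(2),      # A
            (-x + y) / np.sqrt(2),     # B
            -y,                        # C
            1.0 - 1.5 * (x**2 + y**2),  # D
        ]
    )
    refs -= refs.mean(axis=1, keepdims=True)
    refs /= np.linalg.norm(refs, axis=1, keepdims=True)
    return refs


def assign_canonical_labels(ts: TemplateSet) -> TemplateSet:
    """Relabel 4 clusters as A-D by greedy |correlation| matching.

    Each cluster is matched one-to-one to the built-in canonical reference
    map with which it has the highest absolute spatial correlation.  If the
    channel set has no tabulated positions the clusters keep their current
    order and are labeled A-D with a logged notice.
    """
    if ts.k != 4:
        raise ValueError("canonical labeling is defined for K = 4")
    refs = canonical_reference_maps(ts.channel_names)
    if refs is None:
        logger.info(
            "channel set has no canonical positions; labeling clusters "
            "A-D in current (GEV) order"
        )
        order = list(range(4))
    else:
        c = np.abs(ts.maps @ refs.T)  # 4 clusters x 4 references
        c = c.copy()
        order = [-1] * 4  # order[ref] = cluster
        for _ in range(4):
            i, j = np.unravel_index(np.argmax(c), c.shape)
            order[j] = int(i)
            c[i, :] = -1.0
            c[:, j] = -1.0
    return TemplateSet(
        maps=ts.maps[order],
        labels=list(CLASS_LABELS),
        channel_names=list(ts.channel_names),
        gev=ts.gev,
    )


def backfit(rec: Recording, ts: TemplateSet) -> Segmentation:
    """Label every sample with the template of maximal squared correlation.

    No temporal smoothing is applied.  Zero-variance samples carry the
    previous sample's class (class 0 at the start); their count is logged.
    """
    if list(rec.channel_names) != list(ts.channel_names):
        raise ValueError("recording and template channel sets differ")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    proj = ts.maps @ data  # k x n_samples
    labels = np.argmax(proj**2, axis=0)
    flat = np.flatnonzero(data.std(axis=0) == 0)
    if flat.size:
        logger.info(
            "%s: %d zero-variance samples labeled by carry-forward",
            rec.subject_id, flat.size,
        )
        for i in flat:
            labels[i] = labels[i - 1] if i > 0 else 0
    return Segmentation(labels=labels, sampling_rate=rec.sampling_rate)


def compute_parameters(
    seg: Segmentation, n_classes: int = 4, subject_id: str | None = None
) -> MicrostateFeatures:
    """The four microstate parameter families from a segmentation.

    mean duration (ms), occurrence (segments/s), coverage (sample
    fraction) per class, and the 12 ordered transition probabilities
    P(i -> j) = #(segment of i followed by j) / #(segments of i with a
    successor).  Absent classes score 0 throughout.
    """
    labels = seg.labels
    if labels.size == 0:
        raise ValueError("empty segmentation")
    segments = seg.segments
    total_s = labels.size / seg.sampling_rate

    duration = np.zeros(n_classes)
    occurrence = np.zeros(n_classes)
    coverage = np.zeros(n_classes)
    for c in range(n_classes):
        lengths = [e - s for s, e, cls in segments if cls == c]
        if lengths:
            duration[c] = np.mean(lengths) * 1000.0 / seg.sampling_rate
            occurrence[c] = len(lengths) / total_s
            coverage[c] = np.sum(lengths) / labels.size

    counts = np.zeros((n_classes, n_classes))
    seq = [cls for _, _, cls in segments]
    for a, b in zip(seq[:-1], seq[1:]):
        counts[a, b] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = np.where(row_sums > 0, counts / row_sums, 0.0)
    off_diag = tp[~np.eye(n_classes, dtype=bool)]
    return MicrostateFeatures(
        mean_duration_ms=duration,
        occurrence_per_s=occurrence,
        coverage_fraction=coverage,
        transition_prob=off_diag,
        subject_id=subject_id,
    )
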