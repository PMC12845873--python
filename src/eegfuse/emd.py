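"""Empirical mode decomposition and per-IMF statistical features.

Classic EMD sifting: repeatedly subtract the mean of the cubic-spline
upper and lower extrema envelopes until the Cauchy standard-deviation
criterion falls below ``sd_tol``, mirror-extending two extrema per side
to suppress end swings.  The IMF count is standardized to nine per
channel and fourteen conventional statistics are computed per IMF,
giving the channels x 9 x 14 feature tensor (2142 values for 17
channels).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as spstats
from scipy.interpolate import CubicSpline

from .types import EMDFeatureTensor, IMFSet, Recording

logger = logging.getLogger(__name__)

STATISTIC_NAMES = [
    "mean", "max", "min", "q1", "q3", "iqr", "median",
    "variance", "std", "kurtosis", "skewness", "rms",
    "hjorth_activity", "ptp",
]

M_STANDARD = 9


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (endpoints excluded)."""
    d = np.diff(x)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] > 0)) + 1
    return maxima, minima


def _envelope(
    idx: np.ndarray, vals: np.ndarray, n: int
) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended 2 per side."""
    left_n = min(2, idx.size)
    right_n = min(2, idx.size)
    left_pos = -idx[:left_n][::-1]
    left_val = vals[:left_n][::-1]
    right_pos = 2 * (n - 1) - idx[-right_n:][::-1]
    right_val = vals[-right_n:][::-1]
    pos = np.concatenate([left_pos, idx, right_pos])
    val = np.concatenate([left_val, vals, right_val])
    pos, uniq = np.unique(pos, return_index=True)
    val = val[uniq]
    if pos.size < 2:
        return np.full(n, val[0] if val.size else 0.0)
    spline = CubicSpline(pos, val, bc_type="natural")
    return spline(np.arange(n))


def _n_extrema(x: np.ndarray) -> int:
    maxima, minima = _local_extrema(x)
    return maxima.size + minima.size


def sift(
    signal: np.ndarray,
    max_imfs: int = 16,
    sd_tol: float = 0.2,
    max_sift_iter: int = 100,
    source_channel: str | None = None,
) -> IMFSet:
    """Decompose a 1-D signal into intrinsic mode functions.

    Extraction stops when the residual has fewer than 2 extrema (e.g. a
    monotonic trend) or ``max_imfs`` is reached.  The reconstruction
    identity sum(IMFs) + residual = signal holds by construction.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < 4:
        raise ValueError("signal too short to sift")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    n = x.size
    while len(imfs) < max_imfs and _n_extrema(residual) >= 2:
        h = residual.copy()
        for _ in range(max_sift_iter):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _envelope(maxima, h[maxima], n)
            lower = _envelope(minima, h[minima], n)
            m = 0.5 * (upper + lower)
            h_new = h - m
            denom = float(np.sum(h**2))
            sd = float(np.sum(m**2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_tol:
                break
        imfs.append(h)
        residual = residual - h
    return IMFSet(imfs=imfs, residual=residual, source_channel=source_channel)


def standardize_imfs(s: IMFSet, m_target: int = M_STANDARD) -> IMFSet:
    """Keep the first ``m_target`` IMFs, zero-padding on shortfall.

    Early (high-frequency) IMFs carry the oscillatory content, so they are
    the ones retained; missing modes are replaced by zero signals with a
    logged warning, keeping the feature tensor shape fixed.
    """
    if m_target < 1:
        raise ValueError("m_target must be >= 1")
    n = s.residual.size
    imfs = [imf.copy() for imf in s.imfs[:m_target]]
    if len(imfs) < m_target:
        logger.warning(
            "channel %s: %d IMFs extracted, padding to %d with zeros",
            s.source_channel, len(imfs), m_target,
        )
        imfs.extend(np.zeros(n) for _ in range(m_target - len(imfs)))
    residual = s.residual.copy()
    for extra in s.imfs[m_target:]:
        residual = residual + extra
    return IMFSet(imfs=imfs, residual=residual, source_channel=s.source_channel)


def imf_statistics(imf: np.ndarray) -> np.ndarray:
    """The fixed ordered set of 14 conventional statistics of one IMF.

    Variance/std are population (ddof=0); kurtosis is excess; skewness and
    kurtosis are defined as 0 for zero-variance signals; Hjorth activity
    is the signal variance; ptp is the peak-to-peak range.
    """
    x = np.asarray(imf, dtype=float)
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    var = float(np.var(x))
    if var > 0:
        kurt = float(spstats.kurtosis(x, fisher=True, bias=True))
        skew = float(spstats.skew(x, bias=True))
    else:
        kurt = 0.0
        skew = 0.0
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return np.array(
        [
            float(np.mean(x)),
            float(np.max(x)),
            float(np.min(x)),
            float(q1),
            float(q3),
            float(q3 - q1),
            float(med),
            var,
            float(np.sqrt(var)),
            kurt,
            skew,
            float(np.sqrt(np.mean(x**2))),
            var,  # Hjorth activity
            float(np.ptp(x)),
        ]
    )


def emd_feature_tensor(
    rec: Recording,
    m_imfs: int = M_STANDARD,
    sd_tol: float = 0.2,
    max_sift_iter: int = 100,
) -> EMDFeatureTensor:
    """Per-channel EMD + statistics: the N x 9 x 14 feature tensor."""
    values = np.empty((rec.n_channels, m_imfs, len(STATISTIC_NAMES)))
    for i, (name, channel) in enumerate(zip(rec.channel_names, rec.data)):
        imfset = sift(
            channel, sd_tol=sd_tol, max_sift_iter=max_sift_iter,
            source_channel=name,
        )
        imfset = standardize_imfs(imfset, m_imfs)
        for j, imf in enumerate(imfset.imfs):
            values[i, j] = imf_statistics(imf)
    return EMDFeatureTensor(
        values=values,
        channel_names=list(rec.channel_names),
        imf_index=list(range(1, m_imfs + 1)),
        statistic_names=list(STATISTIC_NAMES),
        subject_id=rec.subject_id,
    )


def zero_crossing_rate(x: np.ndarray) -> float:
    """Sign changes per sample; used to verify IMF frequency ordering."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0.0
    return float(np.sum(s[:-1] != s[1:]) / x.size)
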