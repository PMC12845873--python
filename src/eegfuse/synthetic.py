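"""Synthetic resting-state EEG with known microstate dynamics.

The generator emulates the recording setup the pipeline targets: a
17-channel, 250 Hz montage in which the scalp topography at any moment is
one of four fixed templates, modulated by an alpha-band oscillatory
envelope, with segment durations around 80 ms and segment classes driven
by a first-order transition matrix (a semi-Markov chain).  Group contrasts
are planted through the dynamics (class-A duration, B->D transition
probability) and through a slow nonstationary drift term whose amplitude
differs between groups, so that both microstate and EMD feature families
carry signal.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seeds import derive_seed
from .types import GroundTruth, Recording

logger = logging.getLogger(__name__)

#: 17 scalp electrodes of the 10-20 montage used for feature extraction
#: (the two mastoids M1/M2 are reference-only and dropped in preprocessing).
DEFAULT_CHANNELS_17 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
]
DEFAULT_CHANNELS_19 = DEFAULT_CHANNELS_17 + ["M1", "M2"]

K_DEFAULT = 4


@dataclass
class SynthParams:
    """Generator configuration for one subject (or one group).

    ``duration_mean_ms`` may be a scalar (shared by all classes) or a
    per-class sequence.  ``transition_matrix`` must be row-stochastic with
    a zero diagonal; ``None`` means uniform over the other classes.
    ``snr`` is the ratio of template-signal power to total noise power;
    ``drift_amplitude`` scales a slow (0.15-0.9 Hz) per-channel wander
    relative to the signal RMS.
    """

    n_channels: int = 17
    sampling_rate: float = 250.0
    duration: float = 60.0
    templates: np.ndarray | str = "auto"
    duration_mean_ms: float | Sequence[float] = 80.0
    transition_matrix: np.ndarray | None = None
    carrier_freq_hz: float = 10.0
    snr: float = 4.0
    drift_amplitude: float = 0.2
    seed: int = 0
    n_states: int = K_DEFAULT
    channel_names: list[str] | None = None

    def resolved_channel_names(self) -> list[str]:
        if self.channel_names is not None:
            return list(self.channel_names)
        if self.n_channels == 17:
            return list(DEFAULT_CHANNELS_17)
        return [f"ch{i + 1}" for i in range(self.n_channels)]

    def resolved_durations(self) -> np.ndarray:
        d = np.atleast_1d(np.asarray(self.duration_mean_ms, dtype=float))
        if d.size == 1:
            d = np.full(self.n_states, d[0])
        if d.size != self.n_states:
            raise ValueError("duration_mean_ms must be scalar or per-class")
        if np.any(d <= 0):
            raise ValueError("duration_mean_ms must be positive")
        return d

    def resolved_transition_matrix(self) -> np.ndarray:
        k = self.n_states
        if self.transition_matrix is None:
            tm = np.full((k, k), 1.0 / (k - 1))
            np.fill_diagonal(tm, 0.0)
            return tm
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (k, k):
            raise ValueError(f"transition_matrix must be {k}x{k}")
        if np.any(np.diag(tm) != 0):
            raise ValueError("transition_matrix diagonal must be zero")
        rows = tm.sum(axis=1)
        if np.any(rows <= 0):
            raise ValueError("transition_matrix has a degenerate all-zero row")
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("transition_matrix rows must sum to 1")
        return tm

    def validate(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        self.resolved_durations()
        self.resolved_transition_matrix()


def make_templates(n_channels: int, k: int, seed: int) -> np.ndarray:
    """Draw ``k`` zero-mean, unit-norm, mutually uncorrelated topographies.

    Random Gaussian vectors are orthogonalized (QR) and then projected onto
    the zero-mean subspace; the projection perturbs orthogonality only by
    O(1/n_channels), so pairwise spatial correlations stay far inside the
    |r| < 0.5 requirement, deterministically for a given seed.
    """
    if k < 2:
        raise ValueError("need at least 2 templates")
    if k > n_channels:
        raise ValueError("k must not exceed n_channels")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_channels, k))
    q, r = np.linalg.qr(raw)
    # fix signs for determinism across BLAS builds
    q = q * np.sign(np.diag(r))
    maps = q.T  # k x n_channels, orthonormal, zero-mean
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps


def simulate_state_sequence(params: SynthParams) -> GroundTruth:
    """Simulate the per-sample microstate class sequence.

    Segment classes follow ``transition_matrix``; segment lengths are
    gamma-distributed with shape 2 and the requested per-class mean, so
    the coefficient of variation is fixed and sub-sample segments are
    rare (lengths are floored at one sample).
    """
    params.validate()
    rng = np.random.default_rng(derive_seed(params.seed, "states"))
    k = params.n_states
    tm = params.resolved_transition_matrix()
    means_ms = params.resolved_durations()
    n_samples = int(round(params.duration * params.sampling_rate))

    templates = params.templates
    if isinstance(templates, str) and templates == "auto":
        templates = make_templates(
            params.n_channels, k, derive_seed(params.seed, "templates")
        )
    templates = np.asarray(templates, dtype=float)

    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(k))
    pos = 0
    shape = 2.0
    while pos < n_samples:
        mean_samples = means_ms[state] * params.sampling_rate / 1000.0
        length = max(1, int(round(rng.gamma(shape, mean_samples / shape))))
        end = min(pos + length, n_samples)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(k, p=tm[state]))
    return GroundTruth(
        state_sequence=labels,
        templates=templates,
        duration_mean_ms=means_ms,
        transition_matrix=tm,
    )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Per-channel 1/f-amplitude noise, normalized to unit power per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    return pink


def _slow_drift(
    rng: np.random.Generator, shape: tuple[int, int], fs: float
) -> np.ndarray:
    """Band-limited (0.15-0.9 Hz) per-channel wander, unit RMS per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = (freqs >= 0.15) & (freqs <= 0.9)
    spec[:, ~keep] = 0.0
    drift = np.fft.irfft(spec, n=n, axis=1)
    std = drift.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return drift / std


def synthesize_recording(
    params: SynthParams,
    truth: GroundTruth,
    subject_id: str,
    group_label: str | int,
    return_parts: bool = False,
) -> Recording | tuple[Recording, dict[str, np.ndarray]]:
    """Render a Recording from a state sequence.

    data = template(state) x rectified-sinusoid envelope + drift + noise,
    where the noise is an equal-power mix of spatially white Gaussian and
    per-channel 1/f components, scaled so signal power / noise power = snr.
    """
    params.validate()
    templates = np.asarray(truth.templates, dtype=float)
    if templates.shape[1] != params.n_channels:
        raise ValueError("template dimension does not match n_channels")
    n = truth.state_sequence.size
    fs = params.sampling_rate
    t = np.arange(n) / fs
    envelope = np.abs(np.sin(2 * np.pi * params.carrier_freq_hz * t))
    signal = templates[truth.state_sequence].T * envelope[None, :]

    rng = np.random.default_rng(derive_seed(params.seed, "noise"))
    p_signal = float(np.mean(signal**2))
    white = rng.standard_normal(signal.shape)
    pink = _pink_noise(rng, signal.shape)
    noise = np.sqrt(0.5) * white + np.sqrt(0.5) * pink
    noise *= np.sqrt(p_signal / params.snr) / noise.std()

    drift = _slow_drift(rng, signal.shape, fs)
    drift *= params.drift_amplitude * np.sqrt(p_signal)

    rec = Recording(
        subject_id=subject_id,
        group_label=group_label,
        channel_names=params.resolved_channel_names(),
        sampling_rate=fs,
        data=signal + drift + noise,
    )
    if return_parts:
        return rec, {"signal": signal, "noise": noise, "drift": drift}
    return rec


def generate_cohort(
    group_specs: Sequence[tuple[SynthParams, int, str | int]],
    seed: int,
) -> list[tuple[Recording, GroundTruth]]:
    """Generate a multi-group cohort with shared topographic templates.

    Per-subject seeds are derived deterministically from the master seed;
    all groups share one template set (group differences live in the
    dynamics and drift parameters, as in real microstate cohorts).
    """
    if len(group_specs) < 2:
        raise ValueError("need at least 2 groups for classification use")
    for _, n_subjects, _ in group_specs:
        if n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    base = group_specs[0][0]
    shared_templates = base.templates
    if isinstance(shared_templates, str) and shared_templates == "auto":
        shared_templates = make_templates(
            base.n_channels, base.n_states, derive_seed(seed, "templates")
        )

    cohort: list[tuple[Recording, GroundTruth]] = []
    for params, n_subjects, group_label in group_specs:
        for i in range(n_subjects):
            p = copy.deepcopy(params)
            p.templates = shared_templates
            p.seed = derive_seed(seed, f"{group_label}:{i}")
            subject_id = f"{group_label}_{i:03d}"
            truth = simulate_state_sequence(p)
            rec = synthesize_recording(p, truth, subject_id, group_label)
            cohort.append((rec, truth))
    logger.info(
        "generated cohort: %d subjects in %d groups", len(cohort), len(group_specs)
    )
    return cohort


def default_group_specs(
    n_per_group: int = 16,
    duration: float = 60.0,
    snr: float = 4.0,
    microstate_contrast: bool = True,
    drift_contrast: bool = True,
) -> list[tuple[SynthParams, int, str]]:
    """Two-group (HC vs SCZ) study conditions with planted contrasts.

    The patient group has an elevated class-A mean duration (110 vs 80 ms)
    and an elevated B->D transition probability (0.6 vs 1/3), mirroring
    reported microstate abnormalities in schizophrenia; when
    ``drift_contrast`` is set its slow-drift amplitude is also larger
    (1.0 vs 0.2 signal-RMS units) so EMD statistics separate the groups.
    """
    hc = SynthParams(duration=duration, snr=snr, drift_amplitude=0.2)
    scz = SynthParams(duration=duration, snr=snr, drift_amplitude=0.2)
    if microstate_contrast:
        scz.duration_mean_ms = [110.0, 80.0, 80.0, 80.0]
        tm = np.full((4, 4), 1 / 3)
        np.fill_diagonal(tm, 0.0)
        tm[1] = [0.2, 0.0, 0.2, 0.6]  # B -> D elevated
        scz.transition_matrix = tm
    if drift_contrast:
        scz.drift_amplitude = 1.0
    return [(hc, n_per_group, "HC"), (scz, n_per_group, "SCZ")]


def three_group_specs(
    n_per_group: int = 10,
    duration: float = 60.0,
    snr: float = 4.0,
) -> list[tuple[SynthParams, int, str]]:
    """HC / severe / mild three-group conditions with graded contrasts.

    Severity scales the same planted abnormalities: the severe group has
    the stronger class-A duration elevation, B->D transition bias and
    drift amplitude; the mild group sits halfway back toward controls.
    """
    hc = SynthParams(duration=duration, snr=snr, drift_amplitude=0.2)

    def patient(dur_a: float, p_bd: float, drift: float) -> SynthParams:
        tm = np.full((4, 4), 1 / 3)
        np.fill_diagonal(tm, 0.0)
        rest = (1.0 - p_bd) / 2.0
        tm[1] = [rest, 0.0, rest, p_bd]
        return SynthParams(
            duration=duration, snr=snr, drift_amplitude=drift,
            duration_mean_ms=[dur_a, 80.0, 80.0, 80.0],
            transition_matrix=tm,
        )

    return [
        (hc, n_per_group, "HC"),
        (patient(110.0, 0.6, 1.0), n_per_group, "SEVERE"),
        (patient(95.0, 0.45, 0.6), n_per_group, "MILD"),
    ]


def null_group_specs(
    n_per_group: int = 10, duration: float = 30.0, snr: float = 4.0
) -> list[tuple[SynthParams, int, str]]:
    """Two groups with identical generating parameters (chance-level task)."""
    a = SynthParams(duration=duration, snr=snr)
    b = SynthParams(duration=duration, snr=snr)
    return [(a, n_per_group, "G0"), (b, n_per_group, "G1")]


def write_cohort(
    cohort: Sequence[tuple[Recording, GroundTruth]],
    out_dir: str | Path,
    file_format: str = "tsv",
) -> Path:
    """Persist a cohort: one file per subject, a manifest, truth as JSON.

    Returns the manifest path.  ``file_format`` is "tsv" or "edf".
    """
    from .preprocess import write_delimited, write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, truth in cohort:
        fname = f"{rec.subject_id}.{file_format}"
        path = out_dir / fname
        if file_format == "edf":
            write_edf(rec, path)
        else:
            write_delimited(rec, path)
        truth_path = out_dir / f"{rec.subject_id}.truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "state_sequence": truth.state_sequence.tolist(),
                    "templates": truth.templates.tolist(),
                    "duration_mean_ms": np.asarray(
                        truth.duration_mean_ms
                    ).tolist(),
                    "transition_matrix": np.asarray(
                        truth.transition_matrix
                    ).tolist(),
                }
            )
        )
        rows.append((rec.subject_id, rec.group_label, fname))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("subject_id\tgroup_label\tfile\n")
        for sid, grp, fname in rows:
            fh.write(f"{sid}\t{grp}\t{fname}\n")
    return manifest
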