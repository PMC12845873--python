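"""Recording I/O and deterministic preprocessing.

Covers the automatic subset of a clinical EEG cleaning chain: zero-phase
band-pass (0.1-40 Hz) plus 50 Hz notch filtering, resampling to 250 Hz,
bilateral-mastoid re-referencing and reduction to the 17 scalp channels.
Manual steps (ICA, bad-segment rejection, channel interpolation) are out
of scope by design.

File formats: EDF (read through MNE's native reader; written by a minimal
16-bit EDF writer, since no installed library exports EDF) and delimited
numeric matrices (channels as rows, first column the channel name, with a
``# sampling_rate_hz:`` comment line).
"""

from __future__ import annotations

import logging
import struct
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import Recording

logger = logging.getLogger(__name__)

MASTOID_NAMES = ("M1", "M2")


# ---------------------------------------------------------------------------
# delimited matrix I/O


def write_delimited(rec: Recording, path: str | Path, sep: str = "\t") -> Path:
    """Write channels x samples with a channel-name first column."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {rec.sampling_rate:g}\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# group_label: {rec.group_label}\n")
        fh.write("channel" + sep + sep.join(
            f"s{i}" for i in range(rec.n_samples)) + "\n")
        for name, row in zip(rec.channel_names, rec.data):
            fh.write(name + sep + sep.join(f"{v:.17g}" for v in row) + "\n")
    return path


def _read_delimited(path: Path, sep: str) -> Recording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep=sep, float_precision="round_trip")
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"{path}: missing '# sampling_rate_hz:' header line")
    names = df.iloc[:, 0].astype(str).tolist()
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    return Recording(
        subject_id=meta.get("subject_id", path.stem),
        group_label=meta.get("group_label", ""),
        channel_names=names,
        sampling_rate=float(meta["sampling_rate_hz"]),
        data=data,
    )


# ---------------------------------------------------------------------------
# EDF I/O


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a minimal EDF file (16-bit, one 1 s data record per second).

    The recording is zero-padded to an integer number of seconds; the
    per-channel physical range is set symmetrically to the data extremes,
    so the quantization step is range / 65535.
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    # symmetric physical range, stored at the precision the 8-char header
    # field allows and reused for scaling so encode/decode stay consistent
    phys_max = np.array(
        [float(f"{m * 1.0001:.5g}") for m in
         np.maximum(np.abs(data).max(axis=1), 1e-6)]
    )
    dig_max = 32767
    span = 2 * phys_max[:, None]
    scaled = np.round(
        (data + phys_max[:, None]) / span * 65535.0 - 32768.0
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad(f"sub {rec.subject_id} X X X", 80),
            pad(f"grp {rec.group_label}", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        ("".join(n[:16].ljust(16) for n in rec.channel_names)),  # labels
        ("".join(" " * 80 for _ in range(n_ch))),  # transducer
        ("".join("uV".ljust(8) for _ in range(n_ch))),  # dimension
        ("".join(f"{-m:.6g}"[:8].ljust(8) for m in phys_max)),  # phys min
        ("".join(f"{m:.6g}"[:8].ljust(8) for m in phys_max)),  # phys max
        ("".join(str(-dig_max - 1).ljust(8) for _ in range(n_ch))),
        ("".join(str(dig_max).ljust(8) for _ in range(n_ch))),
        ("".join(" " * 80 for _ in range(n_ch))),  # prefiltering
        ("".join(str(spr).ljust(8) for _ in range(n_ch))),
        ("".join(" " * 32 for _ in range(n_ch))),  # reserved
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f.encode("ascii"))
        for r in range(n_rec):
            block = scaled[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    return path


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE stores volts; recordings use microvolts
    return Recording(
        subject_id=path.stem,  # cohort manifests are the id authority
        group_label="",
        channel_names=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        data=data,
    )


def read_recording(path: str | Path, format_hint: str | None = None) -> Recording:
    """Load a Recording from an EDF or delimited matrix file."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format_hint or path.suffix.lstrip(".").lower()
    try:
        if fmt == "edf":
            return _read_edf(path)
        sep = "," if fmt == "csv" else "\t"
        return _read_delimited(path, sep)
    except IOError:
        raise
    except Exception as exc:
        raise IOError(f"failed to parse {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# filtering / resampling / re-referencing


def filter_resample(
    rec: Recording,
    band_low: float = 0.1,
    band_high: float = 40.0,
    notch: float | None = 50.0,
    target_rate: float = 250.0,
) -> Recording:
    """Zero-phase band-pass + notch filter, then resample.

    4th-order Butterworth band-pass (applied forward-backward as SOS) and
    a Q=30 IIR notch; polyphase resampling to ``target_rate``.  Zero-phase
    filtering keeps microstate segment boundaries free of group delay.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 <= band_low < band_high):
        raise ValueError("need 0 <= band_low < band_high")
    if band_high >= nyq:
        raise ValueError("band_high must be below the Nyquist frequency")
    if target_rate > rec.sampling_rate:
        raise ValueError("target_rate must not exceed the original rate")

    sos = sps.butter(
        4, [band_low, band_high], btype="bandpass", fs=rec.sampling_rate,
        output="sos",
    )
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None and notch < nyq:
        b, a = sps.iirnotch(notch, Q=30.0, fs=rec.sampling_rate)
        data = sps.filtfilt(b, a, data, axis=1)

    rate = rec.sampling_rate
    if abs(target_rate - rate) > 1e-9:
        frac = Fraction(target_rate / rate).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        rate = target_rate
    return Recording(
        subject_id=rec.subject_id,
        group_label=rec.group_label,
        channel_names=list(rec.channel_names),
        sampling_rate=rate,
        data=data,
    )


def rereference_select(
    rec: Recording,
    mastoid_channels: tuple[str, str] = MASTOID_NAMES,
    return_reference: bool = False,
) -> Recording | tuple[Recording, np.ndarray]:
    """Bilateral-mastoid re-reference, then drop the mastoid channels.

    Subtracts the mean of the two mastoid signals from every channel and
    removes the mastoids from the montage (19 channels in -> 17 out).  If
    neither mastoid is present (already-reduced synthetic data) the
    recording passes through unchanged with a logged notice.
    """
    present = [m for m in mastoid_channels if m in rec.channel_names]
    if len(present) == 0:
        logger.info(
            "%s: no mastoid channels (%s); re-reference skipped",
            rec.subject_id, mastoid_channels,
        )
        if return_reference:
            return rec, np.zeros(rec.n_samples)
        return rec
    if len(present) != 2:
        raise ValueError(
            f"mastoid channel(s) missing: need both of {mastoid_channels}, "
            f"found {present}"
        )
    idx = [rec.channel_names.index(m) for m in mastoid_channels]
    reference = rec.data[idx].mean(axis=0)
    keep = [i for i in range(rec.n_channels) if i not in idx]
    data = rec.data[keep] - reference[None, :]
    out = Recording(
        subject_id=rec.subject_id,
        group_label=rec.group_label,
        channel_names=[rec.channel_names[i] for i in keep],
        sampling_rate=rec.sampling_rate,
        data=data,
    )
    if return_reference:
        return out, reference
    return out
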