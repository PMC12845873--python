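"""Deterministic seed derivation.

A single master seed fans out to per-stage / per-subject seeds through a
CRC32 hash of ``"master:label"``, keeping every derived seed in [0, 2^31).
"""

from __future__ import annotations

import zlib


def derive_seed(master: int, label: str) -> int:
    """Stable child seed for a named stream under a master seed."""
    return zlib.crc32(f"{int(master)}:{label}".encode()) & 0x7FFFFFFF
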