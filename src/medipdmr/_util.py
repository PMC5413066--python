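"""Shared helpers: seeded substreams and rounding conventions."""

from __future__ import annotations

import math
import zlib

import numpy as np

__all__ = ["substream", "round_half_away"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Derive a named, reproducible RNG substream from one global seed.

    The substream key is the CRC32 of ``label``, so the mapping is stable
    across processes and Python versions (unlike ``hash``).
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties going away from zero.

    Distinct from banker's rounding (``round``): 0.5 -> 1, -0.5 -> -1.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))
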