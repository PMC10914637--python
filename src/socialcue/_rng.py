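"""Deterministic RNG stream derivation.

One top-level integer seed governs a run; every session/ROI gets its own
independent stream derived from (seed, string key) so that adding or
reordering sessions never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def stable_key(*parts: object) -> int:
    """CRC32 of the joined string parts; stable across processes and runs."""
    text = "\x1f".join(str(p) for p in parts)
    return zlib.crc32(text.encode("utf-8"))


def derived_rng(seed: int, *parts: object) -> np.random.Generator:
    """Generator for the stream identified by ``parts`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, stable_key(*parts)]))
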