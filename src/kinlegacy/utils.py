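"""Shared small utilities (seed derivation)."""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic per-purpose generator from one top-level seed.

    Every source of randomness in the package derives its stream from the
    run seed plus a string label, so a single integer reproduces a whole
    run while independent stages never share a stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
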