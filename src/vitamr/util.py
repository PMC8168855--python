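"""Shared small utilities: deterministic RNG stream splitting."""

from __future__ import annotations

from zlib import crc32

import numpy as np


def split_rng(seed: int, *labels: object) -> np.random.Generator:
    """Derive an independent RNG stream from a root seed and a label path.

    Streams are keyed by (seed, crc32(label), ...) through ``SeedSequence``,
    so adding or reordering consumers of one stream never perturbs another —
    per-stage reproducibility survives pipeline refactors.
    """
    key = [int(seed) & 0x7FFFFFFF]
    key.extend(crc32(str(lab).encode()) & 0xFFFFFFFF for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(key))
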