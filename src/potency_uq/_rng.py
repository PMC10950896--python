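"""Seed-stream derivation.

Every operation that consumes randomness derives its own generator from a
master seed plus a string tag, so adding or reordering draws in one
component never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, tag: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, tag); stable across processes."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())]))


def child_seed(seed: int, tag: str) -> int:
    """A derived integer seed below 2**31, for APIs that take plain ints."""
    return int(stream(seed, tag).integers(0, 2**31 - 1))
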