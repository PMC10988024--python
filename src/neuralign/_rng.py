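"""Seed-substream plumbing.

All randomness in the package flows from a single integer seed. Each stage
draws from a named substream so that, e.g., changing the number of bootstrap
replicates never perturbs the simulation draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_seed", "substream_rng"]

_MOD = 2**31


def substream_seed(seed: int, label: str) -> int:
    """Derive a deterministic child seed (< 2**31) from ``seed`` and a label."""
    ss = np.random.SeedSequence([int(seed) % _MOD, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % _MOD)


def substream_rng(seed: int, label: str) -> np.random.Generator:
    """A ``numpy.random.Generator`` for the named substream of ``seed``."""
    return np.random.default_rng(substream_seed(seed, label))
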