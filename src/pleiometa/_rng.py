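"""Deterministic named random sub-streams.

Every stochastic operation in the package takes one integer seed and derives
an independent generator from ``(seed, name)``. Re-running any stage with the
same seed therefore reproduces its output bit-for-bit, and stages do not
perturb each other's streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a stable hash of ``name``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
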