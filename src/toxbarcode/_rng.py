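"""Named-stream random number generation.

Every stochastic component of the package draws from its own substream,
derived from one user-facing seed plus a component name. Adding a new
component (a new name) therefore never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent Generator for component ``name`` under ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for libraries that take plain ints."""
    rng = substream(seed, name)
    return int(rng.integers(0, 2**31 - 1))
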