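"""Seeding policy: one root seed, named substreams per module.

Every stochastic generator in the package draws from a
``numpy.random.Generator`` obtained via :func:`substream`, so that a
single scenario seed reproduces the whole pipeline bit-exactly while
the modules stay statistically independent of each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of a root seed."""
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
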