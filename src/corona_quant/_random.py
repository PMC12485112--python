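"""Deterministic seed splitting.

All stochastic code in the package draws from :func:`substream`, which maps a
user-facing integer seed plus a tuple of string labels to an independent
``numpy.random.Generator``.  The labels are hashed with CRC-32 into the
``spawn_key`` of a :class:`numpy.random.SeedSequence`, so

* the same (seed, labels) pair always yields the same stream, and
* streams for different labels are statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Return an independent RNG for ``labels`` derived from ``seed``."""
    key = tuple(zlib.crc32(lab.encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
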