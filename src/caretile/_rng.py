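"""Deterministic named substreams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``.

    The same (seed, name) always yields an identical stream, and distinct
    names yield statistically independent streams, so pipeline stages can be
    regenerated in isolation.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), tag)))
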