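"""Hierarchical seeding: named substreams derived from one top-level seed.

Each pipeline stage draws from its own substream keyed by a stage name, so
changing the parameters (and hence the number of draws) of one stage never
perturbs the random numbers consumed by another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage ``name`` derived from ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
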