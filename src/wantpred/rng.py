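"""Deterministic named random substreams.

All randomness flows from a single root seed; each pipeline stage draws from
its own named substream so stages are independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the ``name`` substream of root ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    )
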