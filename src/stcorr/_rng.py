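"""Seeded random-stream management.

All randomness in the package flows from a single integer seed through
named child streams, so that every simulation, null distribution and
shuffle is independently reproducible without stream cross-talk.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Derive a named child seed sequence from a root integer seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """A Generator for the named child stream of ``seed``."""
    return np.random.default_rng(child_seed(seed, name))
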