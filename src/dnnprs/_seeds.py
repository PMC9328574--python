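"""Deterministic seed fan-out.

A single master seed drives every stochastic stage (genotype draws, effect
sizes, fold partitions, weight initialisation, dropout, permutations). Each
stage derives its own child seed from the master seed plus a string tag, so any
stage can be replayed in isolation without consuming another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from ``master`` and a sequence of tags.

    Tags may be strings or integers; strings are hashed with crc32 so the
    scheme is stable across processes (unlike Python's salted ``hash``).
    """
    words = [int(master) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, (int, np.integer)):
            words.append(int(tag) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(tag).encode()))
    ss = np.random.SeedSequence(words)
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def derive_rng(master: int, *tags: object) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *tags))
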