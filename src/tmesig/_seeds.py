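"""Deterministic seed fan-out.

Every stochastic operation in the package draws from a Generator obtained via
:func:`spawn_rng`, keyed by the master seed plus a tuple of string/int names.
Streams are therefore reproducible independently of execution order (e.g. one
stream per (sample, template) in the permutation null), and distinct names
never collide on the same stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng"]


def _key(part: str | int) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(str(part).encode("utf-8"))


def spawn_rng(seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    Parameters
    ----------
    seed
        Master seed (any non-negative integer below 2**31).
    names
        Arbitrary labels (strings or ints) identifying the substream.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key(n) for n in names))
    return np.random.default_rng(ss)
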