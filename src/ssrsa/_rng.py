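"""Seed handling.

Every stochastic operation in the package draws from a generator obtained via
:func:`substream`, which derives an independent child stream from a single
integer seed and a tuple of string keys naming the consumer.  This makes each
component reproducible in isolation: regenerating only the "epochs-noise"
stream, say, does not depend on how many draws the mesh generator made.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a generator for the named sub-stream of ``seed``.

    Parameters
    ----------
    seed:
        Master integer seed.
    *keys:
        Hashable labels (converted to str) identifying the consumer, e.g.
        ``substream(seed, "activations", "L7")``.
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    entropy += [zlib.crc32(str(k).encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
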