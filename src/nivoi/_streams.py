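"""Named, independent random streams derived from one master seed.

Every stochastic stage (PSA, trial outer loop, trial inner loop, ...) pulls
its generator from :func:`stream`, so stages are independently reproducible:
changing the draw count of one loop never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a CRC32 of the name, so the mapping is stable
    across runs and platforms.
    """
    if not (0 <= int(seed) < 2**63):
        raise ValueError("seed must be a nonnegative integer")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
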