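"""Named random substreams.

All randomness in the package flows from a single integer seed. Each generator
draws from its own substream, derived from the seed plus a stable name, so that
re-running one stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``name``.

    The mapping (seed, name) -> stream is stable across runs and platforms;
    distinct names yield statistically independent streams.
    """
    if not (0 <= int(seed) < 2**63):
        raise ValueError(f"seed must be a non-negative 63-bit integer, got {seed}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
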