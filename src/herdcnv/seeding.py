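"""Deterministic seed-splitting.

Every stochastic stage draws its generator from the root seed plus the stage
name hashed into a substream key, so adding a stage never perturbs the
randomness of earlier stages.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream_seed(root_seed: int, stage: str) -> int:
    """A 31-bit stage seed derived from (root_seed, stage name)."""
    key = zlib.crc32(stage.encode("utf-8"))
    mixed = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, key])
    return int(mixed.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(root_seed: int, stage: str) -> np.random.Generator:
    """Generator for one named stage of a run."""
    return np.random.default_rng(substream_seed(root_seed, stage))
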