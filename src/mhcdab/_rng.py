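"""Seed-stream helpers.

A single integer seed is propagated to named sub-streams, one per pipeline
stage, so each stage is independently reproducible: changing the read
simulation does not perturb the microsatellite panel drawn from the same
master seed.
"""

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named sub-stream of ``seed``."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def spawn_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain ints."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
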