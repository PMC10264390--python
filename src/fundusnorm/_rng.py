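"""Counter-based seed splitting.

All randomness in the package flows from one explicit integer seed. Derived
streams are keyed by (seed, *keys) so per-image / per-stage streams do not
depend on generation order.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed_sequence(seed: int, *keys: object) -> np.random.SeedSequence:
    """Build a SeedSequence keyed by a master seed plus arbitrary labels."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.SeedSequence(entropy)


def derive_rng(seed: int, *keys: object) -> np.random.Generator:
    """Independent generator for the stream identified by ``keys``."""
    return np.random.default_rng(derive_seed_sequence(seed, *keys))
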