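"""Small shared utilities (deterministic seed derivation)."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(*keys) -> int:
    """Derive a child seed (< 2**31) deterministically from mixed keys.

    Strings are hashed with CRC32 so per-stage/per-dyad/per-reservoir seeds
    are stable regardless of execution order.
    """
    parts = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            parts.append(int(k) & 0xFFFFFFFF)
        else:
            parts.append(zlib.crc32(str(k).encode()))
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))
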