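"""Named random substreams derived from one master seed."""
from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, *keys: object) -> np.random.Generator:
    """A generator seeded reproducibly by (seed, *keys).

    Each key is hashed so independent analysis stages (trial draws, ensemble
    draws, shuffles, fold splits, ...) consume independent streams that are
    all pinned by the single master seed.
    """
    ints = [
        int.from_bytes(hashlib.sha256(repr(k).encode()).digest()[:4], "little")
        for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *ints]))
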