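"""Small shared helpers (seed derivation)."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of (stage name, global seed), below 2**31.

    Lets a pipeline run record one global seed while every stage draws from
    an independent, individually replayable stream.
    """
    digest = hashlib.sha256(f"{stage}:{int(seed)}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, stage))
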