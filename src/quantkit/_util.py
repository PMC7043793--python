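"""Small shared helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic per-stage sub-seed below 2**31.

    Hashing (seed, label) means adding or reordering stages never perturbs
    another stage's random stream.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))
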