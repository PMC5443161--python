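"""Deterministic seed derivation.

A single run seed is expanded into independent per-component streams
(per fold, per pair, per subsample) via SHA-256 of the seed plus a tag
path, so adding a component never perturbs the streams of the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(seed: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a tag path."""
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for t in tags:
        h.update(b"/")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(seed: int, *tags: object) -> np.random.Generator:
    """A numpy Generator for the (seed, tag-path) stream."""
    return np.random.default_rng(derive_seed(seed, *tags))
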