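"""Deterministic, order-independent random-stream derivation.

Every stochastic component derives its own generator from a master seed
plus a tuple of string/int tokens (e.g. ``("fingerprint", subject_id)``),
hashed with SHA-256. This makes cohorts and splits reproducible bit-for-bit
and independent of the order in which subjects or classes are processed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(master_seed: int, *tokens) -> int:
    """Map (master_seed, tokens...) to a stable 63-bit integer seed."""
    key = repr((int(master_seed),) + tuple(tokens)).encode("utf-8")
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "little") >> 1


def derive_rng(master_seed: int, *tokens) -> np.random.Generator:
    """A fresh :class:`numpy.random.Generator` for one labelled stream."""
    return np.random.default_rng(np.random.SeedSequence(derive_seed(master_seed, *tokens)))
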