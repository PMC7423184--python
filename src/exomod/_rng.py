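"""Deterministic, order-independent random stream derivation.

Every stochastic component of the pipeline derives its generator from a
master seed plus a tuple of string/int tokens (stage name, gene symbol,
contrast, ...).  Derivation goes through SHA-256 so streams are stable
across Python processes and independent of iteration order.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Map (master_seed, tokens) to a 63-bit child seed via SHA-256."""
    payload = repr((int(master_seed),) + tuple(str(t) for t in tokens))
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") >> 1


def derive_rng(master_seed: int, *tokens: object) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from a hashed token stream."""
    return np.random.default_rng(derive_seed(master_seed, *tokens))
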