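"""Deterministic derivation of named child seeds from one master seed.

Every stochastic stage (universe assembly, train/test split, weight
initialisation, per-epoch shuffling, sampling) draws its own child seed so
that stages are independently reproducible and re-orderable.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a child seed from ``master_seed`` and a stage label.

    Stable across sessions and platforms (SHA-256 based); the result fits in
    a signed 32-bit integer so it is usable with any RNG API.
    """
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
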