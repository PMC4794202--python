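"""Deterministic seed derivation.

A master seed plus a tuple of string/int tags is hashed (SHA-256) into a
31-bit child seed, so every stage, subject and replicate gets an
independent stream and parallel execution cannot change results.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *tags: object) -> int:
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
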