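"""Deterministic seed fan-out shared across the pipeline stages."""

from __future__ import annotations

import zlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *keys) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and a stage key.

    Counter-based: the sub-stream depends only on (master, keys), so
    adding pipeline stages never perturbs earlier stages' randomness.
    """
    tag = repr((int(master), keys)).encode()
    return zlib.crc32(tag) % (2**31)
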