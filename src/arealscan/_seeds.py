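"""Deterministic named sub-seed derivation.

All Monte Carlo components take one integer master seed.  Named substreams
(``scan``, ``meet``, ``sensitivity-impute-<t>`` ...) are derived from it so
that toggling one analysis never perturbs another's random draws.
"""

from __future__ import annotations

import zlib

__all__ = ["substream"]


def substream(seed: int, *labels: object) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a label path.

    The derivation is a CRC-32 chain, which is stable across platforms and
    Python versions (unlike ``hash``).
    """
    h = int(seed) & 0x7FFFFFFF
    for lab in labels:
        h = zlib.crc32(repr(lab).encode("utf-8"), h) & 0x7FFFFFFF
    return h
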