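"""Deterministic per-stage seed derivation.

Every stochastic stage draws its seed from the master seed plus a stable
string key, so no stage depends on global random state or on the order in
which other stages run.
"""

from __future__ import annotations

import zlib

_MODULUS = 2**31 - 1


def derive_seed(master_seed: int, *names: object) -> int:
    """Derive a child seed from ``master_seed`` and a path of stage names.

    The derivation is a CRC-32 hash of the joined names mixed with the
    master seed; it is stable across processes and platforms and always
    returns a non-negative integer below 2**31 - 1.
    """
    key = "/".join(str(n) for n in names)
    h = zlib.crc32(key.encode("utf-8"))
    return (int(master_seed) * 1_000_003 + h) % _MODULUS
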