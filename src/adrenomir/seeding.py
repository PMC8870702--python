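"""Deterministic seed fan-out.

A single integer master seed is expanded into per-stage (and per-repetition,
per-sample) child seeds by hashing the master seed together with a path of
string keys. Children are independent of each other and reproducible across
platforms and processes (SHA-256, not Python's salted ``hash``).
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]

_MOD = 2**31  # keep child seeds in the range any RNG seed parameter accepts


def child_seed(master: int, *keys: object) -> int:
    """Derive a child seed from ``master`` and a path of string-able keys.

    Parameters
    ----------
    master : int
        Non-negative master seed.
    *keys : object
        Path components, e.g. ``child_seed(7, "search", "split", 12)``.

    Returns
    -------
    int in ``[0, 2**31)``.
    """
    if master < 0:
        raise ValueError("master seed must be >= 0")
    payload = "/".join([str(int(master))] + [str(k) for k in keys])
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
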