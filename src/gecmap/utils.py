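"""Small shared helpers."""

from __future__ import annotations


def derive_seed(master: int, *tags: object) -> int:
    """Deterministic child seed below 2^31, decorrelated from the master.

    A simple multiplicative string hash over the master seed and tags;
    stable across platforms and Python processes (unlike ``hash``).
    """
    h = (int(master) & 0x7FFFFFFF) or 1
    for tag in tags:
        for ch in str(tag):
            h = (h * 1000003 + ord(ch)) % (2**31 - 1)
    return int(h)
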