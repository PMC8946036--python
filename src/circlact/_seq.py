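"""Tiny sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_occurrences(haystack: str, needle: str) -> int:
    """Number of (possibly overlapping) occurrences of needle in haystack."""
    n, i = 0, haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n
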