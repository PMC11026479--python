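"""Small sequence utilities shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance over the shared prefix length (lengths must match)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))
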