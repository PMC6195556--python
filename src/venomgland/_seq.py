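"""Small shared sequence utilities (reverse complement, phred codecs)."""

from __future__ import annotations

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PHRED_OFFSET = 33  # Sanger / phred+33


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_RC)[::-1]


def phred_to_str(quals) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def str_to_phred(s: str) -> tuple:
    return tuple(ord(c) - PHRED_OFFSET for c in s)
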