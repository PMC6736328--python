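"""Low-level nucleotide-string helpers shared across the assembler.

All sequences are plain upper-case ACGT strings; anything else is treated
as ambiguous and handled by splitting (see :func:`clean_fragments`).
"""

from __future__ import annotations

import re
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_AMBIGUOUS = re.compile(r"[^ACGT]+")


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq``."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def clean_fragments(read: str) -> Iterator[str]:
    """Split a read at ambiguous (non-ACGT) characters.

    Each maximal ACGT run is yielded separately; the ambiguous bases
    themselves are discarded.
    """
    for frag in _AMBIGUOUS.split(read.upper()):
        if frag:
            yield frag


def kmers_of(seq: str, k: int) -> Iterator[str]:
    """All overlapping k-mers of ``seq`` in order (empty if len < k)."""
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def at_fraction(seq: str) -> float:
    """Fraction of A/T nucleotides; 0.0 for the empty string."""
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


def hamming(a: str, b: str) -> int:
    """Hamming distance over the first ``min(len(a), len(b))`` positions."""
    return sum(x != y for x, y in zip(a, b))
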