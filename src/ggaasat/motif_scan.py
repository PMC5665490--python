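"""Literal 4-mer motif scanning on both strands of a nucleotide sequence.

The core binding element of ETS-family transcription factors is the 4-mer
GGAA; its reverse-strand mirror on the forward sequence is TTCC.  Scanning is
implemented as a forward-strand search for the two literal 4-mers — the
reverse strand is never materialized, which is equivalent and memory-light.
Windows containing N never match (the reference is N-padded at assembly gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

MOTIF_LENGTH = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif hit: a 4-bp half-open interval with the strand it matches on.

    ``strand`` is "+" when the forward sequence equals the motif (GGAA) and
    "-" when it equals the motif's reverse complement (TTCC).
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end - self.start != MOTIF_LENGTH:
            raise ValueError("motif occurrence must span exactly 4 bp")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def _find_all(seq: str, pattern: str) -> List[int]:
    out: List[int] = []
    i = seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def find_motif_occurrences(
    seq: str, chrom: str, motif: str = "GGAA"
) -> List[MotifOccurrence]:
    """All positions where a 4-mer equals ``motif`` (+) or its reverse
    complement (-), sorted by start.

    ``seq`` must be uppercase over {A,C,G,T,N}.  Opposite-strand occurrences
    may interleave but can never share a start (the two literals differ).
    """
    motif = motif.upper()
    if len(motif) != MOTIF_LENGTH:
        raise ValueError("motif must be a 4-mer")
    rc = reverse_complement(motif)
    fwd = _find_all(seq, motif)
    if rc == motif:  # palindromic motif: a single strand-agnostic hit list
        return [MotifOccurrence(chrom, i, i + MOTIF_LENGTH, "+") for i in fwd]
    rev = _find_all(seq, rc)

    out: List[MotifOccurrence] = []
    fi = ri = 0
    while fi < len(fwd) or ri < len(rev):
        if ri >= len(rev) or (fi < len(fwd) and fwd[fi] < rev[ri]):
            out.append(MotifOccurrence(chrom, fwd[fi], fwd[fi] + MOTIF_LENGTH, "+"))
            fi += 1
        else:
            out.append(MotifOccurrence(chrom, rev[ri], rev[ri] + MOTIF_LENGTH, "-"))
            ri += 1
    return out
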