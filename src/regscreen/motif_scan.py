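"""Degenerate-motif scanning on both strands with palindrome strand collapse.

A motif is an IUPAC nucleotide string; each letter denotes a set of bases.
A genomic base matches a motif letter when the base's own IUPAC set is
contained in the letter's set.  Concretely: A/C/G/T match any letter whose
set includes them, while an assembly ``N`` matches only a motif ``N`` — an
ambiguous genome position is never allowed to satisfy a specific motif
letter, which keeps hit counts honest in gap regions.

DNA palindromes (motifs equal to their own reverse complement, such as the
LmbU box TCGCCGGCGA) match both strands at every occurrence; those
strand-duplicate hits are collapsed into a single record with strand ``.``,
because a binding *site* is one piece of double-stranded DNA, not two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .genome_io import AnnotatedGenome, IUPAC_LETTERS

#: IUPAC letter -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; involutive."""
    seq = seq.upper()
    bad = set(seq) - IUPAC_LETTERS
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """A degenerate binding-site motif given as an IUPAC string."""

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if len(self.pattern) < 4:
            raise ValueError("motif must be at least 4 bases long")
        bad = set(self.pattern) - IUPAC_LETTERS
        if bad:
            raise ValueError(f"non-IUPAC characters in motif: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def is_palindromic(self) -> bool:
        """True iff the pattern equals its own reverse complement."""
        return self.pattern == reverse_complement(self.pattern)


#: The extended LmbU binding box used for the genome-wide screen.
DEFAULT_MOTIF = Motif("TCGCCGGCGA")
#: The shorter conserved palindromic core.
CORE_MOTIF = Motif("CGCCGGCG")


@dataclass(frozen=True)
class MotifHit:
    """One genomic motif occurrence.

    ``start``/``end`` are 1-based inclusive; ``matched`` records the plus-strand
    genomic bases over the interval.  ``strand`` is ``+`` or ``-`` for
    non-palindromic motifs and ``.`` for strand-collapsed palindromic hits.
    For a hit spanning the origin of a circular contig, ``end`` exceeds the
    contig length and wraps.
    """

    contig: str
    start: int
    end: int
    strand: str
    matched: str


def _letter_class(letter: str) -> str:
    """Regex character class matching genome bases contained in ``letter``.

    Genome sequences contain A/C/G/T and ambiguity codes; only exact-set
    containment matches, so e.g. genome N matches motif N alone.
    """
    bases = sorted(IUPAC_SETS[letter])
    chars = "".join(bases)
    # every genome ambiguity code whose set is a subset of this letter's set
    for g, gset in IUPAC_SETS.items():
        if g not in "ACGT" and gset <= IUPAC_SETS[letter]:
            chars += g
    return f"[{chars}]"


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(_letter_class(c) for c in pattern) + "))")


def scan(genome: AnnotatedGenome, motif: Motif | str = DEFAULT_MOTIF) -> list[MotifHit]:
    """Find all motif occurrences on both strands of every contig.

    Overlapping occurrences are all reported (no masking).  For palindromic
    motifs the coincident +/- hits are reported once with strand ``.``.
    Circular contigs are scanned across the origin.  A motif longer than a
    contig simply yields no hits there.
    """
    if isinstance(motif, str):
        motif = Motif(motif)
    m = len(motif)
    palindromic = motif.is_palindromic
    fwd_re = _pattern_regex(motif.pattern)
    rev_re = None if palindromic else _pattern_regex(reverse_complement(motif.pattern))

    hits: list[MotifHit] = []
    for contig, seq in genome.contigs.items():
        L = len(seq)
        if m > L:
            continue
        search_seq = seq + seq[: m - 1] if genome.is_circular(contig) else seq
        max_start0 = L - 1 if genome.is_circular(contig) else L - m

        def emit(regex: re.Pattern, strand: str) -> None:
            for match in regex.finditer(search_seq):
                s0 = match.start()
                if s0 > max_start0:
                    break
                hits.append(
                    MotifHit(
                        contig=contig,
                        start=s0 + 1,
                        end=s0 + m,
                        strand=strand,
                        matched=match.group(1),
                    )
                )

        if palindromic:
            emit(fwd_re, ".")
        else:
            emit(fwd_re, "+")
            emit(rev_re, "-")
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def count_hits(hits: Iterable[MotifHit]) -> int:
    """Number of motif occurrences (strand-collapsed for palindromes)."""
    return sum(1 for _ in hits)
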