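"""Shared fixtures and the independent brute-force motif-scan oracle."""

from __future__ import annotations

import numpy as np
import pytest

from regscreen import AnnotatedGenome, GeneRecord

# --- independent naive oracle (deliberately not importing scan internals) ---

_ORACLE_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_ORACLE_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def oracle_revcomp(seq: str) -> str:
    return "".join(_ORACLE_COMP[c] for c in reversed(seq))


# genome base matches when its own base set is contained in the letter's set;
# table precomputed because the oracle runs over millions of positions
_MATCH = {
    (g, c): set(_ORACLE_SETS[g]) <= set(_ORACLE_SETS[c])
    for g in _ORACLE_SETS
    for c in _ORACLE_SETS
}


def _base_matches(genome_char: str, motif_char: str) -> bool:
    return _MATCH[genome_char, motif_char]


def oracle_scan(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Position-by-position O(n·m) scan; returns 1-based (start, strand) pairs.

    Palindromic patterns are reported once per interval with strand '.'.
    """
    m = len(pattern)
    rc = oracle_revcomp(pattern)
    palindromic = pattern == rc
    out = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        fwd = all(_MATCH[window[j], pattern[j]] for j in range(m))
        if palindromic:
            if fwd:
                out.append((i + 1, "."))
            continue
        if fwd:
            out.append((i + 1, "+"))
        if all(_MATCH[window[j], rc[j]] for j in range(m)):
            out.append((i + 1, "-"))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def gc_rich_sequence(rng):
    def make(length: int, gc: float = 0.7, seed: int | None = None) -> str:
        r = rng if seed is None else np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(r.choice(bases, size=length, p=p))

    return make


@pytest.fixture
def small_genome():
    """A 12-kb contig with four genes: a 3-gene plus-strand operon and a
    minus-strand monocistronic gene, with plenty of upstream room."""
    seq = ("ACGT" * 3000)
    genes = [
        GeneRecord("g1", "c1", 2000, 2899, "+", product="LAL family transcriptional regulator"),
        GeneRecord("g2", "c1", 2910, 3509, "+", product="MFS transporter"),
        GeneRecord("g3", "c1", 3540, 4439, "+", product="hypothetical protein"),
        GeneRecord("g4", "c1", 6000, 6899, "-", product="RNA polymerase sigma factor"),
    ]
    return AnnotatedGenome(contigs={"c1": seq}, genes=genes)
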