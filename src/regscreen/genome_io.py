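"""Genome and annotation I/O with fixed coordinate conventions.

All coordinates held in memory are 1-based and inclusive on both ends, the
GFF3 convention.  BED output is 0-based half-open; the conversion happens
only at the I/O boundary (``write_hits_bed`` / ``read_hits_bed``) and is its
own inverse.

The in-memory substrate for the screen is :class:`AnnotatedGenome`: contig
sequences (uppercase A/C/G/T plus IUPAC ambiguity codes) together with
:class:`GeneRecord` annotations.  Contigs default to linear topology, which
is the rule for *Streptomyces* chromosomes; circular topology may be set per
contig and enables origin-spanning motif windows downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: The 15-letter IUPAC nucleotide alphabet (no gaps).
IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")


class GenomeFormatError(ValueError):
    """Raised for malformed FASTA/GFF3/BED input."""


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated gene.

    ``start``/``end`` are 1-based inclusive genomic coordinates with
    ``start <= end`` regardless of strand; ``strand`` orients the reading
    direction, so the translational start site (TRSS) is ``start`` on the
    ``+`` strand and ``end`` on the ``-`` strand.
    """

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeFormatError(
                f"gene {self.locus_tag!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise GenomeFormatError(
                f"gene {self.locus_tag!r}: need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.length < 3:
            raise GenomeFormatError(f"gene {self.locus_tag!r}: length < 3")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def trss(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end


@dataclass
class AnnotatedGenome:
    """Contig sequences plus gene annotations."""

    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)
    topology: dict[str, str] = field(default_factory=dict)  # contig -> linear|circular

    def __post_init__(self) -> None:
        for name in self.contigs:
            self.topology.setdefault(name, "linear")
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_tag in seen:
                raise GenomeFormatError(f"duplicate locus_tag {g.locus_tag!r}")
            seen.add(g.locus_tag)
            if g.contig not in self.contigs:
                raise GenomeFormatError(
                    f"gene {g.locus_tag!r} placed on unknown contig {g.contig!r}"
                )
            if g.end > len(self.contigs[g.contig]):
                raise GenomeFormatError(
                    f"gene {g.locus_tag!r} extends past end of contig {g.contig!r}"
                )

    def is_circular(self, contig: str) -> bool:
        return self.topology.get(contig, "linear") == "circular"

    def gene(self, locus_tag: str) -> GeneRecord:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)

    def with_genes(self, genes: Sequence[GeneRecord]) -> "AnnotatedGenome":
        return AnnotatedGenome(
            contigs=dict(self.contigs),
            genes=sorted(genes, key=lambda g: (g.contig, g.start)),
            topology=dict(self.topology),
        )


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - IUPAC_LETTERS
    if bad:
        raise GenomeFormatError(
            f"record {record_id!r}: non-IUPAC characters {sorted(bad)!r}"
        )
    if not seq:
        raise GenomeFormatError(f"record {record_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path) -> AnnotatedGenome:
    """Read a (multi-)FASTA file into an :class:`AnnotatedGenome` (contigs only).

    Sequences are uppercased and RNA U is normalized to T.  Duplicate record
    ids, empty files and non-IUPAC characters raise :class:`GenomeFormatError`.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GenomeFormatError(f"duplicate contig id {rec.id!r}")
        contigs[rec.id] = _normalize_sequence(str(rec.seq), rec.id)
    if not contigs:
        raise GenomeFormatError(f"{path}: no FASTA records found")
    return AnnotatedGenome(contigs=contigs)


def read_gff3(path: str | Path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Attach gene records from a GFF3 file to ``genome``.

    One :class:`GeneRecord` is produced per ``locus_tag``, taken from ``gene``
    or ``CDS`` features (``gene`` wins when both carry the same tag).
    Coordinates are taken verbatim (GFF3 is already 1-based inclusive).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_tag: dict[str, GeneRecord] = {}
    preferred: dict[str, str] = {}  # locus_tag -> featuretype that produced it
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        tags = feat.attributes.get("locus_tag")
        if not tags:
            raise GenomeFormatError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start}-{feat.end} "
                "has no locus_tag attribute"
            )
        tag = tags[0]
        if feat.end < feat.start:
            raise GenomeFormatError(f"feature {tag!r}: end < start")
        if feat.seqid not in genome.contigs:
            raise GenomeFormatError(f"feature {tag!r} on unknown contig {feat.seqid!r}")
        if tag in by_tag and preferred[tag] == "gene":
            continue  # keep the gene-level record
        product = feat.attributes.get("product", [""])[0]
        by_tag[tag] = GeneRecord(
            locus_tag=tag,
            contig=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
            product=product,
        )
        preferred[tag] = feat.featuretype
    return genome.with_genes(list(by_tag.values()))


def write_genome_fasta(genome: AnnotatedGenome, path: str | Path, width: int = 70) -> None:
    """Write contigs as FASTA with fixed line width (deterministic output)."""
    with open(path, "w") as fh:
        for name in genome.contigs:
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genes_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write gene records as a minimal GFF3 file (round-trips with read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in sorted(genome.genes, key=lambda g: (g.contig, g.start)):
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig}\tregscreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_hits_bed(hits: Iterable, path: str | Path) -> None:
    """Write motif hits as BED6 (0-based half-open; name = matched bases).

    An empty hit list produces an empty file: BED has no header line.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start - 1}\t{h.end}\t{h.matched}\t.\t{h.strand}\n"
            )


def read_hits_bed(path: str | Path) -> list:
    """Read BED6 back into MotifHit records (inverse of :func:`write_hits_bed`)."""
    from .motif_scan import MotifHit

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise GenomeFormatError(f"{path}:{lineno}: expected 6 BED columns")
            contig, start0, end, name, _score, strand = parts[:6]
            hits.append(
                MotifHit(
                    contig=contig,
                    start=int(start0) + 1,
                    end=int(end),
                    strand=strand,
                    matched=name,
                )
            )
    return hits


def write_table_tsv(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write a list of dict-like rows as TSV with a header row."""
    rows = list(rows)
    if not rows:
        Path(path).write_text("")
        return
    fieldnames = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_table_tsv(path: str | Path) -> list[dict]:
    """Read a TSV with header into a list of string-valued dicts."""
    with open(path, newline="") as fh:
        return [dict(row) for row in csv.DictReader(fh, delimiter="\t")]
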