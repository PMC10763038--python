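"""Operon inference, regulatory windows and candidate-site classification.

The screen keeps a motif hit only when it can plausibly sit in a promoter:
inside the window running from 600 bp upstream to 100 bp downstream of a
gene's translational start site (TRSS), and only for genes that actually own
a promoter — the first gene of an operon, or a monocistronic gene.  Hits
upstream of operon-internal genes lie inside the transcription unit and are
discarded.

Positions are reported in the signed TRSS-relative convention used for
bacterial promoter annotation: −1 is the base immediately 5' of the start
codon, +1 the first base of the start codon; there is no position 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import AnnotatedGenome, GeneRecord
from .motif_scan import MotifHit


@dataclass
class OperonModel:
    """Genes grouped into operons (each list in reading order, first gene first)."""

    operons: list[list[str]]
    max_intergenic_gap: int = 50

    def __post_init__(self) -> None:
        self._first = {op[0] for op in self.operons}
        self._member: dict[str, int] = {}
        for i, op in enumerate(self.operons):
            for tag in op:
                if tag in self._member:
                    raise ValueError(f"gene {tag!r} appears in two operons")
                self._member[tag] = i

    def is_first(self, locus_tag: str) -> bool:
        """True for operon-leading and monocistronic genes (promoter owners)."""
        return locus_tag in self._first

    def operon_of(self, locus_tag: str) -> list[str]:
        return self.operons[self._member[locus_tag]]


def infer_operons(genome: AnnotatedGenome, max_intergenic_gap: int = 50) -> OperonModel:
    """Group co-directional, closely spaced genes into operons.

    Adjacent genes on the same contig and strand are merged when the
    intergenic gap (bases strictly between them) is at most
    ``max_intergenic_gap``; a strand flip always breaks the operon.  Each
    operon list is ordered in its reading direction, so for minus-strand
    operons the 5'-most (highest-coordinate) gene comes first.
    """
    if max_intergenic_gap < 0:
        raise ValueError("max_intergenic_gap must be >= 0")
    operons: list[list[GeneRecord]] = []
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in sorted(genome.genes, key=lambda g: (g.contig, g.start)):
        by_contig.setdefault(g.contig, []).append(g)
    for genes in by_contig.values():
        run: list[GeneRecord] = []
        for g in genes:
            if run and g.strand == run[-1].strand and (g.start - run[-1].end - 1) <= max_intergenic_gap:
                run.append(g)
            else:
                if run:
                    operons.append(run)
                run = [g]
        if run:
            operons.append(run)
    lists = []
    for run in operons:
        tags = [g.locus_tag for g in run]
        if run[0].strand == "-":
            tags.reverse()  # reading order: 5'-most gene first
        lists.append(tags)
    return OperonModel(operons=lists, max_intergenic_gap=max_intergenic_gap)


@dataclass(frozen=True)
class RegulatoryWindow:
    """The candidate promoter region around one gene's TRSS."""

    locus_tag: str
    contig: str
    start: int  # genomic, 1-based inclusive (truncated at linear contig ends)
    end: int
    strand: str
    upstream_extent: int
    downstream_extent: int
    eligible: bool  # gene is operon-first or monocistronic


def build_windows(
    genome: AnnotatedGenome,
    operons: OperonModel,
    upstream: int = 600,
    downstream: int = 100,
) -> list[RegulatoryWindow]:
    """One window per gene, spanning −upstream..+downstream around the TRSS.

    Only operon-first and monocistronic genes get ``eligible=True``; windows
    are truncated at the ends of linear contigs.
    """
    windows = []
    for g in genome.genes:
        L = len(genome.contigs[g.contig])
        if g.strand == "+":
            lo, hi = g.start - upstream, g.start + downstream - 1
        else:
            lo, hi = g.end - downstream + 1, g.end + upstream
        if not genome.is_circular(g.contig):
            lo, hi = max(1, lo), min(L, hi)
        windows.append(
            RegulatoryWindow(
                locus_tag=g.locus_tag,
                contig=g.contig,
                start=lo,
                end=hi,
                strand=g.strand,
                upstream_extent=upstream,
                downstream_extent=downstream,
                eligible=operons.is_first(g.locus_tag),
            )
        )
    return windows


def _rel(p: int, gene: GeneRecord) -> int:
    """Signed position of genomic coordinate ``p`` relative to the TRSS (no zero)."""
    if gene.strand == "+":
        s = gene.trss
        return p - s + 1 if p >= s else p - s
    e = gene.trss
    return e - p + 1 if p <= e else e - p


def relative_position(hit: MotifHit, gene: GeneRecord) -> tuple[int, int]:
    """Signed TRSS-relative interval of a hit, reported 5'→3' along the gene.

    −1 is the base immediately upstream of the start codon and +1 its first
    base; position 0 does not exist.
    """
    if hit.contig != gene.contig:
        raise ValueError(
            f"hit on contig {hit.contig!r} but gene {gene.locus_tag!r} on {gene.contig!r}"
        )
    if gene.strand == "+":
        return _rel(hit.start, gene), _rel(hit.end, gene)
    return _rel(hit.end, gene), _rel(hit.start, gene)


CATEGORIES = ("regulator", "transporter/resistance", "sigma_factor", "other")


def tag_category(product_text: str) -> str:
    """Coarse functional category from the product annotation (keyword rules)."""
    text = product_text.lower()
    if "transcriptional regulator" in text:
        return "regulator"
    if any(k in text for k in ("transporter", "permease", "substrate-binding")):
        return "transporter/resistance"
    if "sigma factor" in text:
        return "sigma_factor"
    return "other"


@dataclass(frozen=True)
class CandidateSite:
    """A motif hit assigned to one gene's regulatory window."""

    locus_tag: str
    rel_start: int
    rel_end: int
    hit: MotifHit
    product: str = ""
    category: str = "other"

    def as_row(self) -> dict:
        return {
            "locus_tag": self.locus_tag,
            "product": self.product,
            "category": self.category,
            "rel_start": self.rel_start,
            "rel_end": self.rel_end,
            "contig": self.hit.contig,
            "start": self.hit.start,
            "end": self.hit.end,
            "strand": self.hit.strand,
            "matched": self.hit.matched,
        }


def classify_hits(
    hits: Iterable[MotifHit],
    windows: Sequence[RegulatoryWindow],
    genome: AnnotatedGenome,
) -> list[CandidateSite]:
    """Assign hits wholly contained in eligible windows to candidate sites.

    A hit inside the windows of two genes (divergent promoters) yields one
    site per gene.  Containment is whole-hit: a hit merely overlapping the
    window edge is excluded.
    """
    gene_by_tag = {g.locus_tag: g for g in genome.genes}
    by_contig: dict[str, list[RegulatoryWindow]] = {}
    for w in windows:
        if w.eligible:
            by_contig.setdefault(w.contig, []).append(w)
    sites: list[CandidateSite] = []
    for hit in hits:
        for w in by_contig.get(hit.contig, ()):
            if w.start <= hit.start and hit.end <= w.end:
                gene = gene_by_tag[w.locus_tag]
                rel_start, rel_end = relative_position(hit, gene)
                sites.append(
                    CandidateSite(
                        locus_tag=w.locus_tag,
                        rel_start=rel_start,
                        rel_end=rel_end,
                        hit=hit,
                        product=gene.product,
                        category=tag_category(gene.product),
                    )
                )
    sites.sort(key=lambda s: (s.locus_tag, s.rel_start))
    return sites


def screen(
    genome: AnnotatedGenome,
    motif=None,
    upstream: int = 600,
    downstream: int = 100,
    max_intergenic_gap: int = 50,
) -> tuple[list[MotifHit], list[CandidateSite]]:
    """Run the full funnel: scan → operon inference → window classification.

    Returns the genome-wide hit list and the candidate sites surviving the
    regulatory-window and operon filters (|sites| counts gene assignments,
    so a divergent-promoter hit may appear twice).
    """
    from .motif_scan import DEFAULT_MOTIF, scan

    hits = scan(genome, motif if motif is not None else DEFAULT_MOTIF)
    operons = infer_operons(genome, max_intergenic_gap=max_intergenic_gap)
    windows = build_windows(genome, operons, upstream=upstream, downstream=downstream)
    return hits, classify_hits(hits, windows, genome)
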