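"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data the analysis consumes:

* :func:`simulate_genome` — a high-GC (70%) bacterial chromosome with
  operonic gene structure and motif instances planted at known positions,
  some inside eligible regulatory windows, some upstream of operon-internal
  genes, some intergenic.  The background is rejection-sampled to contain
  zero spontaneous motif occurrences, so the planted truth table is an
  exact oracle for the scan and the window classifier.
* :func:`simulate_ct` — qPCR threshold-cycle tables with a stable reference
  gene and specified true fold changes (Ct = baseline − log2(expression) +
  Gaussian cycle noise).
* :func:`simulate_reporter` — linear A375 reporter time courses with
  Gaussian read noise around specified true activities.

All generators are pure functions of their spec (which carries the seed):
the same spec yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .expression_quant import CtTable
from .genome_io import (
    AnnotatedGenome,
    GeneRecord,
    write_genes_gff3,
    write_genome_fasta,
    write_table_tsv,
)
from .motif_scan import IUPAC_SETS, Motif, scan
from .regulatory_filter import OperonModel, RegulatoryWindow, build_windows
from .reporter_assay import ReporterSeries

_PRODUCT_POOL = (
    "LAL family transcriptional regulator",
    "TetR family transcriptional regulator",
    "AraC family transcriptional regulator",
    "MFS transporter",
    "ABC transporter permease",
    "ABC transporter substrate-binding protein",
    "RNA polymerase sigma factor",
    "methyltransferase",
    "thioesterase",
    "hypothetical protein",
)

SiteKind = Literal["in_window", "operon_internal", "intergenic"]


@dataclass(frozen=True)
class PlantedSiteSpec:
    """One motif instance to plant.

    ``locus_tag`` (gene kinds) and ``position`` may be left ``None`` for the
    generator to choose deterministically.  For gene kinds ``position`` is
    the signed TRSS-relative start of the site; for intergenic sites it is
    an absolute 1-based genomic start.
    """

    kind: SiteKind
    locus_tag: str | None = None
    position: int | None = None


@dataclass
class GenomeSimSpec:
    """Parameters of the simulated chromosome (defaults: 200 kb, 150 genes)."""

    contig_length: int = 200_000
    n_contigs: int = 1
    gc_content: float = 0.70
    n_genes: int = 150
    gene_length_mean: float = 900.0
    gene_length_sd: float = 300.0
    gene_length_min: int = 150
    operon_geometric_p: float = 0.5  # operon size ~ min(Geom(p), operon_size_max)
    operon_size_max: int = 5
    intra_operon_gap: tuple[int, int] = (5, 50)
    intergenic_gap: tuple[int, int] = (150, 1200)
    motif: str = "TCGCCGGCGA"
    upstream: int = 600
    downstream: int = 100
    n_in_window_sites: int = 6
    n_operon_internal_sites: int = 3
    n_intergenic_sites: int = 4
    planted_sites: list[PlantedSiteSpec] | None = None
    seed: int = 0

    def site_list(self) -> list[PlantedSiteSpec]:
        if self.planted_sites is not None:
            return list(self.planted_sites)
        return (
            [PlantedSiteSpec("in_window")] * self.n_in_window_sites
            + [PlantedSiteSpec("operon_internal")] * self.n_operon_internal_sites
            + [PlantedSiteSpec("intergenic")] * self.n_intergenic_sites
        )


@dataclass
class SimulatedGenome:
    """Generator output: the genome, its construction-time operons, and truth."""

    genome: AnnotatedGenome
    operons: OperonModel
    truth: pd.DataFrame  # one row per planted site

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fna",
            "gff3": outdir / "genes.gff3",
            "truth": outdir / "truth.tsv",
        }
        write_genome_fasta(self.genome, paths["fasta"])
        write_genes_gff3(self.genome, paths["gff3"])
        write_table_tsv(self.truth.to_dict("records"), paths["truth"])
        return paths


class SitePlacementError(RuntimeError):
    """Raised when planted sites cannot be placed under the constraints."""


def _rel_to_genomic_start(gene: GeneRecord, rel_start: int, m: int) -> int:
    """Genomic start (ascending coordinate) of a site whose 5' end is at ``rel_start``."""
    if rel_start == 0:
        raise ValueError("signed relative positions have no zero")
    if gene.strand == "+":
        s = gene.trss
        return s + rel_start - 1 if rel_start > 0 else s + rel_start
    e = gene.trss
    # rel_start is the 5'-most position along the gene = highest genomic coord
    p_hi = e - rel_start + 1 if rel_start > 0 else e - rel_start
    return p_hi - m + 1


def _layout_genes(spec: GenomeSimSpec, rng: np.random.Generator):
    """Place operonic genes along the contigs; returns (genes, operon lists)."""
    genes: list[GeneRecord] = []
    operon_lists: list[list[str]] = []
    counter = 0
    per_contig = spec.n_genes // spec.n_contigs
    for ci in range(spec.n_contigs):
        contig = f"chrSim{ci + 1}" if spec.n_contigs > 1 else "chrSim"
        target = per_contig + (spec.n_genes % spec.n_contigs if ci == 0 else 0)
        pos = int(rng.integers(800, 1500))
        placed = 0
        while placed < target:
            size = min(int(rng.geometric(spec.operon_geometric_p)), spec.operon_size_max)
            size = min(size, target - placed)
            strand = "+" if rng.random() < 0.5 else "-"
            run: list[GeneRecord] = []
            ok = True
            p = pos
            for i in range(size):
                length = int(
                    np.clip(
                        rng.normal(spec.gene_length_mean, spec.gene_length_sd),
                        spec.gene_length_min,
                        4000,
                    )
                )
                end = p + length - 1
                if end > spec.contig_length - 800:
                    ok = False
                    break
                counter += 1
                run.append(
                    GeneRecord(
                        locus_tag=f"SIM_{counter:04d}",
                        contig=contig,
                        start=p,
                        end=end,
                        strand=strand,
                        product=str(rng.choice(_PRODUCT_POOL)),
                    )
                )
                p = end + 1 + int(rng.integers(*spec.intra_operon_gap))
            if not ok:
                if not run:
                    break
                counter -= len(run)  # drop the partial operon
                break
            genes.extend(run)
            placed += size
            tags = [g.locus_tag for g in run]
            if strand == "-":
                tags.reverse()
            operon_lists.append(tags)
            pos = run[-1].end + 1 + int(rng.integers(*spec.intergenic_gap))
            if pos > spec.contig_length - 2000:
                break
    if not genes:
        raise SitePlacementError("contig too short to place any genes")
    return genes, operon_lists


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _choose_intervals(
    spec: GenomeSimSpec,
    sites: Sequence[PlantedSiteSpec],
    windows: Sequence[RegulatoryWindow],
    genome: AnnotatedGenome,
    operons: OperonModel,
    rng: np.random.Generator,
):
    """Pick non-overlapping genomic intervals honouring each site's category."""
    m = len(spec.motif)
    gene_by_tag = {g.locus_tag: g for g in genome.genes}
    win_by_tag = {w.locus_tag: w for w in windows}
    eligible = [w for w in windows if w.eligible]
    chosen: list[tuple[str, int, int]] = []  # (contig, start, end)

    def overlaps_chosen(contig: str, start: int, end: int) -> bool:
        # keep a full motif-length margin so planted sites cannot compound
        return any(
            c == contig and start <= ce + m and cs - m <= end for c, cs, ce in chosen
        )

    def inside_eligible(contig: str, start: int, end: int, except_tag: str | None) -> bool:
        return any(
            w.contig == contig and w.start <= start and end <= w.end
            and w.locus_tag != except_tag
            for w in eligible
        )

    def overlaps_any_window(contig: str, start: int, end: int) -> bool:
        return any(
            w.contig == contig and start <= w.end and w.start <= end for w in windows
        )

    placements = []
    for site in sites:
        placed = False
        for _ in range(500):
            if site.kind == "intergenic":
                contig = str(rng.choice(list(genome.contigs)))
                L = len(genome.contigs[contig])
                if site.position is not None:
                    start = site.position
                else:
                    start = int(rng.integers(1, L - m + 2))
                end = start + m - 1
                if site.position is None and overlaps_any_window(contig, start, end):
                    continue
                if inside_eligible(contig, start, end, None) or overlaps_chosen(
                    contig, start, end
                ):
                    if site.position is not None:
                        raise SitePlacementError(
                            f"requested intergenic position {site.position} conflicts"
                        )
                    continue
                placements.append((site.kind, None, contig, start, end))
                placed = True
                break
            # gene-anchored kinds
            if site.locus_tag is not None:
                tag = site.locus_tag
            elif site.kind == "in_window":
                pool = [w.locus_tag for w in eligible]
                tag = str(rng.choice(pool))
            else:
                pool = [w.locus_tag for w in windows if not w.eligible]
                if not pool:
                    raise SitePlacementError("no operon-internal genes to anchor site")
                tag = str(rng.choice(pool))
            gene = gene_by_tag[tag]
            w = win_by_tag[tag]
            if site.kind == "in_window" and not w.eligible:
                raise SitePlacementError(f"gene {tag!r} is operon-internal; its window is ineligible")
            if site.position is not None:
                start = _rel_to_genomic_start(gene, site.position, m)
            else:
                start = int(rng.integers(w.start, w.end - m + 2))
            end = start + m - 1
            if not (w.start <= start and end <= w.end):
                if site.position is not None:
                    raise SitePlacementError(
                        f"relative position {site.position} does not fit window of {tag!r}"
                    )
                continue
            bad = inside_eligible(
                gene.contig, start, end, tag if site.kind == "in_window" else None
            ) or overlaps_chosen(gene.contig, start, end)
            if bad:
                if site.position is not None:
                    raise SitePlacementError(
                        f"site at {site.position} relative to {tag!r} conflicts with "
                        "another window or site"
                    )
                continue
            placements.append((site.kind, tag, gene.contig, start, end))
            placed = True
            break
        if not placed:
            raise SitePlacementError(
                f"could not place {site.kind} site after 500 attempts"
            )
        chosen.append((placements[-1][2], placements[-1][3], placements[-1][4]))
    return placements


def _realize_motif(pattern: str, rng: np.random.Generator) -> str:
    """A concrete A/C/G/T instance of an IUPAC pattern."""
    return "".join(
        c if c in "ACGT" else str(rng.choice(sorted(IUPAC_SETS[c]))) for c in pattern
    )


def simulate_genome(spec: GenomeSimSpec) -> SimulatedGenome:
    """Generate the chromosome, plant the motif instances, return truth.

    The background is re-sampled wherever a spontaneous motif occurrence
    appears (on either strand), so the final hit set equals the planted set
    exactly; sites that cannot be placed without conflict raise
    :class:`SitePlacementError`.
    """
    rng = np.random.default_rng(spec.seed)
    motif = Motif(spec.motif)
    m = len(motif)
    genes, operon_lists = _layout_genes(spec, rng)

    # background sequence first (needed for the AnnotatedGenome container)
    contig_names = sorted({g.contig for g in genes})
    seq_arrays = {
        name: _random_bases(spec.contig_length, spec.gc_content, rng)
        for name in contig_names
    }
    genome = AnnotatedGenome(
        contigs={n: a.tobytes().decode() for n, a in seq_arrays.items()},
        genes=sorted(genes, key=lambda g: (g.contig, g.start)),
    )
    operons = OperonModel(operons=operon_lists)
    windows = build_windows(
        genome, operons, upstream=spec.upstream, downstream=spec.downstream
    )

    placements = _choose_intervals(spec, spec.site_list(), windows, genome, operons, rng)

    # write the motif instances into the sequence and lock those positions
    locked: dict[str, np.ndarray] = {
        n: np.zeros(spec.contig_length, dtype=bool) for n in contig_names
    }
    for kind, tag, contig, start, end in placements:
        instance = _realize_motif(motif.pattern, rng)
        seq_arrays[contig][start - 1 : end] = np.frombuffer(
            instance.encode(), dtype="S1"
        )
        locked[contig][start - 1 : end] = True

    planted_keys = {(c, s) for _, _, c, s, _ in placements}
    for round_ in range(60):
        genome = AnnotatedGenome(
            contigs={n: a.tobytes().decode() for n, a in seq_arrays.items()},
            genes=genome.genes,
        )
        spurious = [
            h for h in scan(genome, motif) if (h.contig, h.start) not in planted_keys
        ]
        if not spurious:
            break
        for h in spurious:
            idx = np.arange(h.start - 1, h.end)
            free = idx[~locked[h.contig][idx]]
            if free.size == 0:
                raise SitePlacementError(
                    "spontaneous motif occurrence consists entirely of planted bases"
                )
            seq_arrays[h.contig][free] = _random_bases(
                free.size, spec.gc_content, rng
            )
    else:
        raise SitePlacementError("could not purge spontaneous motif occurrences")

    from .regulatory_filter import relative_position
    from .motif_scan import MotifHit

    gene_by_tag = {g.locus_tag: g for g in genome.genes}
    rows = []
    for i, (kind, tag, contig, start, end) in enumerate(placements, 1):
        if tag is not None:
            gene = gene_by_tag[tag]
            hit = MotifHit(contig=contig, start=start, end=end, strand=".", matched="")
            rel_start, rel_end = relative_position(hit, gene)
        else:
            rel_start = rel_end = None
        rows.append(
            {
                "site_id": f"site_{i:03d}",
                "kind": kind,
                "contig": contig,
                "start": start,
                "end": end,
                "locus_tag": tag or "",
                "rel_start": rel_start,
                "rel_end": rel_end,
                "in_window": kind == "in_window",
            }
        )
    truth = pd.DataFrame(rows)
    return SimulatedGenome(genome=genome, operons=operons, truth=truth)


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass
class CtSimSpec:
    """True expression state behind a simulated Ct table.

    ``true_folds`` maps (strain, gene) to the expression of that gene in
    that strain relative to the control; unlisted pairs default to 1.  Cycle
    noise is i.i.d. Gaussian on the Ct scale (default SD 0.2 cycles, a
    typical qPCR technical-replicate spread), with triplicate measurements.
    """

    genes: Sequence[str]
    strains: Sequence[str]
    true_folds: dict[tuple[str, str], float] = field(default_factory=dict)
    control: str = "WT"
    reference: str = "hrdB"
    baseline_ct: float = 22.0
    reference_ct: float = 16.0
    replicates: int = 3
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.true_folds.values()):
            raise ValueError("true fold changes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def simulate_ct(spec: CtSimSpec) -> CtTable:
    """Ct = baseline − log2(expression) + Normal(0, SD), per replicate.

    The reference gene has expression 1 in every strain, so its expected Ct
    is constant; control-strain target genes also sit at expression 1.
    """
    rng = np.random.default_rng(spec.seed)
    strains = list(spec.strains)
    if spec.control not in strains:
        strains = [spec.control] + strains
    rows = []
    for strain in strains:
        for gene in [spec.reference, *spec.genes]:
            if gene == spec.reference or strain == spec.control:
                expr = 1.0
            else:
                expr = spec.true_folds.get((strain, gene), 1.0)
            base = spec.reference_ct if gene == spec.reference else spec.baseline_ct
            mean_ct = base - np.log2(expr)
            for rep in range(1, spec.replicates + 1):
                rows.append(
                    {
                        "strain": strain,
                        "gene": gene,
                        "replicate": rep,
                        "Ct": float(mean_ct + rng.normal(0.0, spec.noise_sd)),
                    }
                )
    return CtTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Reporter time series


@dataclass
class ReporterSimSpec:
    """True activities (ΔA375·min⁻¹·mg⁻¹) behind simulated reporter traces."""

    true_activities: dict[str, float]
    baseline_a375: float = 0.05
    noise_sd: float = 0.002
    n_points: int = 10
    dt_min: float = 1.0
    protein_mg: dict[str, float] | float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.true_activities.values()):
            raise ValueError("true activities must be >= 0")


def simulate_reporter(spec: ReporterSimSpec) -> dict[str, ReporterSeries]:
    """Linear A375 traces with Gaussian read noise, one per strain."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_points) * spec.dt_min
    out = {}
    for strain, activity in spec.true_activities.items():
        mass = (
            spec.protein_mg.get(strain, 1.0)
            if isinstance(spec.protein_mg, dict)
            else spec.protein_mg
        )
        y = spec.baseline_a375 + activity * mass * t + rng.normal(
            0.0, spec.noise_sd, size=t.shape
        )
        out[strain] = ReporterSeries(
            strain=strain, time_min=t.tolist(), a375=y.tolist(), protein_mg=mass
        )
    return out
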