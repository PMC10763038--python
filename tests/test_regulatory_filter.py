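"""Operon inference, window construction, signed positions, classification."""

import pytest

from regscreen import (
    AnnotatedGenome,
    GeneRecord,
    Motif,
    MotifHit,
    build_windows,
    classify_hits,
    infer_operons,
    relative_position,
    tag_category,
)
from regscreen.synthetic_data import GenomeSimSpec, simulate_genome
from regscreen.regulatory_filter import screen


def _genome(genes, length=20000, contig="c1"):
    return AnnotatedGenome(contigs={contig: "ACGT" * (length // 4)}, genes=genes)


class TestInferOperons:
    def test_codirectional_close_genes_merge(self):
        g = _genome(
            [
                GeneRecord("a", "c1", 1000, 1999, "+"),
                GeneRecord("b", "c1", 2010, 2999, "+"),  # gap 10
                GeneRecord("c", "c1", 3020, 3999, "+"),  # gap 20
            ]
        )
        ops = infer_operons(g, max_intergenic_gap=50)
        assert ops.operons == [["a", "b", "c"]]

    def test_gap_boundary(self):
        # gap of exactly 50 merges; 51 splits
        for gap, expected in [(50, 1), (51, 2)]:
            g = _genome(
                [
                    GeneRecord("a", "c1", 1000, 1999, "+"),
                    GeneRecord("b", "c1", 2000 + gap, 2999 + gap, "+"),
                ]
            )
            assert len(infer_operons(g).operons) == expected

    def test_strand_flip_always_breaks(self):
        g = _genome(
            [
                GeneRecord("a", "c1", 1000, 1999, "+"),
                GeneRecord("b", "c1", 2005, 2999, "-"),  # gap 5, opposite strand
            ]
        )
        assert infer_operons(g).operons == [["a"], ["b"]]

    def test_minus_strand_operon_reading_order(self):
        # on the minus strand the 5'-most gene has the highest coordinates
        g = _genome(
            [
                GeneRecord("a", "c1", 1000, 1999, "-"),
                GeneRecord("b", "c1", 2010, 2999, "-"),
            ]
        )
        ops = infer_operons(g)
        assert ops.operons == [["b", "a"]]
        assert ops.is_first("b") and not ops.is_first("a")


class TestBuildWindows:
    def test_plus_strand_arithmetic(self):
        g = _genome([GeneRecord("a", "c1", 1000, 1999, "+")])
        (w,) = build_windows(g, infer_operons(g))
        assert (w.start, w.end) == (400, 1099)
        assert w.eligible

    def test_minus_strand_mirror_arithmetic(self):
        g = _genome([GeneRecord("a", "c1", 4000, 5000, "-")])
        (w,) = build_windows(g, infer_operons(g))
        assert (w.start, w.end) == (4901, 5600)

    def test_truncation_at_contig_start(self):
        g = _genome([GeneRecord("a", "c1", 300, 1299, "+")])
        (w,) = build_windows(g, infer_operons(g))
        assert (w.start, w.end) == (1, 399)

    def test_internal_gene_window_ineligible(self):
        g = _genome(
            [
                GeneRecord("a", "c1", 1000, 1999, "+"),
                GeneRecord("b", "c1", 2010, 2999, "+"),
            ]
        )
        windows = {w.locus_tag: w for w in build_windows(g, infer_operons(g))}
        assert windows["a"].eligible and not windows["b"].eligible


class TestRelativePosition:
    def test_upstream_interval_matches_published_convention(self):
        # a site 316..307 bases 5' of the start codon
        gene = GeneRecord("SLINC_0469", "c1", 5000, 7963, "+")
        hit = MotifHit("c1", 4684, 4693, ".", "TCGCCGGCGA")
        assert relative_position(hit, gene) == (-316, -307)

    def test_downstream_interval_inside_gene(self):
        gene = GeneRecord("SLINC_4499", "c1", 5000, 5557, "+")
        hit = MotifHit("c1", 5088, 5097, ".", "TCGCCGGCGA")
        assert relative_position(hit, gene) == (89, 98)

    def test_first_base_of_start_codon_is_plus_one(self):
        gene = GeneRecord("g", "c1", 5000, 5999, "+")
        hit = MotifHit("c1", 5000, 5009, ".", "TCGCCGGCGA")
        assert relative_position(hit, gene)[0] == 1

    def test_no_position_zero_across_trss(self):
        gene = GeneRecord("g", "c1", 5000, 5999, "+")
        hit = MotifHit("c1", 4995, 5004, ".", "TCGCCGGCGA")
        rel = relative_position(hit, gene)
        assert rel == (-5, 5)  # spans the boundary: 5 upstream + 5 coding bases

    def test_minus_strand_intervals(self):
        gene = GeneRecord("g", "c1", 4000, 5000, "-")
        up = MotifHit("c1", 5010, 5019, ".", "TCGCCGGCGA")
        assert relative_position(up, gene) == (-19, -10)
        down = MotifHit("c1", 4991, 5000, ".", "TCGCCGGCGA")
        assert relative_position(down, gene) == (1, 10)

    def test_contig_mismatch_rejected(self):
        gene = GeneRecord("g", "c1", 5000, 5999, "+")
        hit = MotifHit("c2", 4684, 4693, ".", "TCGCCGGCGA")
        with pytest.raises(ValueError):
            relative_position(hit, gene)

    def test_round_trip_with_generator_inverse(self):
        from regscreen.synthetic_data import _rel_to_genomic_start

        gene_p = GeneRecord("g", "c1", 5000, 5999, "+")
        gene_m = GeneRecord("h", "c1", 5000, 5999, "-")
        for gene in (gene_p, gene_m):
            for rel in (-600, -307, -1, 1, 42, 91):
                start = _rel_to_genomic_start(gene, rel, 10)
                hit = MotifHit("c1", start, start + 9, ".", "")
                assert relative_position(hit, gene)[0] == rel


class TestClassifyHits:
    def _setup(self):
        gene = GeneRecord("a", "c1", 5000, 5999, "+")
        g = _genome([gene])
        windows = build_windows(g, infer_operons(g))
        return g, gene, windows

    @pytest.mark.parametrize(
        "rel_start,included",
        [(-601, False), (-600, True), (91, True), (92, False)],
    )
    def test_window_boundaries(self, rel_start, included):
        g, gene, windows = self._setup()
        start = 5000 + rel_start if rel_start < 0 else 5000 + rel_start - 1
        hit = MotifHit("c1", start, start + 9, ".", "X" * 10)
        sites = classify_hits([hit], windows, g)
        assert bool(sites) is included

    def test_divergent_promoters_yield_two_sites(self):
        genes = [
            GeneRecord("left", "c1", 2000, 2999, "-"),
            GeneRecord("right", "c1", 3200, 4199, "+"),
        ]
        g = _genome(genes)
        windows = build_windows(g, infer_operons(g))
        hit = MotifHit("c1", 3100, 3109, ".", "X" * 10)  # between the two TRSSs
        sites = classify_hits([hit], windows, g)
        assert sorted(s.locus_tag for s in sites) == ["left", "right"]

    def test_ineligible_window_excluded(self):
        genes = [
            GeneRecord("a", "c1", 5000, 5999, "+"),
            GeneRecord("b", "c1", 6010, 6999, "+"),  # operon-internal
        ]
        g = _genome(genes)
        windows = build_windows(g, infer_operons(g))
        hit = MotifHit("c1", 5950, 5959, ".", "X" * 10)  # upstream of b, inside operon
        assert classify_hits([hit], windows, g) == []

    def test_funnel_monotonicity_on_simulated_genome(self):
        sim = simulate_genome(GenomeSimSpec(seed=11))
        hits, sites = screen(sim.genome)
        assert len(sites) <= len(hits)


class TestTagCategory:
    @pytest.mark.parametrize(
        "product,category",
        [
            ("LAL family transcriptional regulator", "regulator"),
            ("RNA polymerase sigma factor", "sigma_factor"),
            ("methyltransferase", "other"),
            ("MFS transporter", "transporter/resistance"),
            ("ABC transporter substrate-binding protein", "transporter/resistance"),
            ("ABC TRANSPORTER PERMEASE", "transporter/resistance"),
            ("", "other"),
        ],
    )
    def test_keyword_rules(self, product, category):
        assert tag_category(product) == category
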