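"""Intergenic spacing, closure, NCR detection, inventories and codon calls."""

import pytest

from mitobipart.annotation_stats import (
    ClosureError,
    closure_length,
    detect_ncrs,
    gene_inventory,
    infer_codons,
    intergenic_spacings,
    length_conservation,
    trna_size_range,
)
from mitobipart.genome_model import (
    CircularChromosome,
    FeatureAnnotation,
    GeneClass,
    GenomeAnnotation,
    parse_gene_table,
)
from mitobipart.reference import (
    TABLE1_CHROMOSOME_I,
    TABLE1_CHROMOSOME_II,
    reference_intergenic_column,
)


class TestIntergenicSpacings:
    def test_every_printed_spacer_reproduced(self, reference_annotations):
        """The computed spacer after each feature equals the published column,
        including the wrap-around values (13 and 12 nt) closing each circle."""
        for ann, table in zip(
            reference_annotations, (TABLE1_CHROMOSOME_I, TABLE1_CHROMOSOME_II)
        ):
            printed = reference_intergenic_column(table)
            records = intergenic_spacings(ann)
            assert len(records) == len(ann.features)  # n records on a circle
            for f, rec in zip(ann.features, records):
                assert rec.spacing == printed[(f.gene_name, f.start)], f.gene_name
            assert records[-1].wraps_origin

    @pytest.mark.parametrize(
        "rows,expected",
        [
            ("cox1 1 1536\ntrnC 1535 1590", -2),  # 1-nt-style overlap scores negative
            ("trnD 2406 2461\ntrnG 2568 2623", 106),
            ("a 1 10\nb 11 20", 0),  # abutting genes score 0
        ],
    )
    def test_spacing_convention(self, rows, expected):
        ann = parse_gene_table(rows, chromosome_length=7659)
        assert intergenic_spacings(ann)[0].spacing == expected

    def test_excessive_overlap_flagged(self):
        ann = parse_gene_table("a 1 100\nb 10 30", chromosome_length=200)
        rec = intergenic_spacings(ann)[0]
        assert rec.spacing == -91 and rec.violation

    def test_conservation_identity(self, reference_annotations):
        """Sum of feature lengths plus all spacers equals the chromosome length."""
        for ann in reference_annotations:
            implied, declared = length_conservation(ann)
            assert implied == declared


class TestClosure:
    def test_reference_closures(self, reference_annotations):
        chr1, chr2 = reference_annotations
        assert closure_length(chr1, 13) == 7659
        assert closure_length(chr2, 12) == 7647

    def test_single_feature(self):
        ann = parse_gene_table("g 1 100", chromosome_length=100)
        assert closure_length(ann, 0) == 100

    def test_disagreement_raises(self, reference_annotations):
        with pytest.raises(ClosureError, match="7660.*7659"):
            closure_length(reference_annotations[0], 14)


class TestDetectNcrs:
    def test_reference_ncrs(self, reference_annotations):
        chr1, chr2 = reference_annotations
        (n1,) = detect_ncrs(chr1, min_len=200)
        assert (n1.start, n1.end, n1.length) == (6866, 7336, 471)
        (n2,) = detect_ncrs(chr2, min_len=200)
        assert (n2.start, n2.end, n2.length) == (6988, 7476, 489)

    def test_threshold_500_finds_nothing(self, reference_annotations):
        assert detect_ncrs(reference_annotations[0], min_len=500) == []

    def test_monotone_in_threshold(self, reference_annotations):
        for ann in reference_annotations:
            counts = [len(detect_ncrs(ann, min_len=t)) for t in (50, 100, 200, 472, 500)]
            assert counts == sorted(counts, reverse=True)

    def test_naming_in_coordinate_order(self):
        ann = parse_gene_table("a 1 10\nb 311 320\nc 621 630", chromosome_length=1000)
        ncrs = detect_ncrs(ann, min_len=200)
        assert [(n.gene_name, n.start) for n in ncrs] == [("NCR1", 11), ("NCR2", 321)]


class TestGeneInventory:
    def test_reference_genome_inventory(self, reference_annotations):
        inv = gene_inventory(reference_annotations)
        assert inv.distinct[GeneClass.PCG] == 12
        assert inv.distinct[GeneClass.TRNA] == 22
        assert inv.distinct[GeneClass.RRNA] == 2
        assert inv.duplicated_across == ["cox2", "trnD", "trnG", "trnH"]
        assert inv.missing_canonical == ["atp8"]

    def test_chromosome_ii_alone(self, reference_annotations):
        inv = gene_inventory([reference_annotations[1]])
        counts = inv.per_chromosome["chromosome_II"]
        assert counts[GeneClass.PCG] == 7
        assert counts[GeneClass.TRNA] == 16
        assert counts[GeneClass.RRNA] == 0

    def test_empty_input(self):
        inv = gene_inventory([])
        assert inv.per_chromosome == {} and inv.duplicated_across == []

    def test_within_chromosome_duplicates_reported_separately(self):
        ann = GenomeAnnotation(
            CircularChromosome("c", 500),
            [
                FeatureAnnotation("trnX", GeneClass.TRNA, 1, 55),
                FeatureAnnotation("trnX", GeneClass.TRNA, 100, 154),
            ],
        )
        inv = gene_inventory([ann])
        assert inv.duplicated_across == []
        assert inv.duplicated_within == {"c": ["trnX"]}


def _pcg(seq, name="g"):
    chrom = CircularChromosome("c", len(seq), seq)
    feat = FeatureAnnotation(name, GeneClass.PCG, 1, len(seq))
    return chrom, feat


class TestInferCodons:
    def test_complete_stop(self):
        chrom, feat = _pcg("ATG" + "TTC" * 10 + "TAG")
        call = infer_codons(chrom, feat)
        assert (call.start_codon, call.stop_codon, call.complete) == ("ATG", "TAG", True)

    def test_incomplete_t(self):
        # span = 3 + 3*k + 1 == 1 (mod 3), trailing T
        chrom, feat = _pcg("ATA" + "GGA" * 5 + "T")
        call = infer_codons(chrom, feat)
        assert (call.stop_codon, call.complete) == ("T", False)

    def test_incomplete_ta(self):
        chrom, feat = _pcg("ATT" + "GGA" * 5 + "TA")
        call = infer_codons(chrom, feat)
        assert (call.stop_codon, call.complete) == ("TA", False)

    def test_bad_trailing_base_raises(self):
        chrom, feat = _pcg("ATGTTCTTCG")  # span 10 ends in G
        with pytest.raises(ValueError, match="incomplete-stop"):
            infer_codons(chrom, feat)

    def test_disallowed_start_flagged(self):
        chrom, feat = _pcg("GTG" + "TTC" * 10 + "TAA")
        assert not infer_codons(chrom, feat).start_codon_allowed
        assert infer_codons(chrom, feat, allowed_starts={"GTG"}).start_codon_allowed

    def test_internal_stop_detected(self):
        chrom, feat = _pcg("ATG" + "TAA" + "TTC" * 9 + "TAG")
        with pytest.raises(ValueError, match="internal in-frame stop"):
            infer_codons(chrom, feat, check_internal_stops=True)


class TestTrnaSizeRange:
    def test_reference_range(self, reference_annotations):
        mn, mx, mn_gene, mx_gene = trna_size_range(reference_annotations)
        assert (mn, mx) == (53, 70)
        assert mn_gene in ("trnW", "trnP") and mx_gene == "trnV"

    def test_chromosome_i_only(self, reference_annotations):
        mn, mx, mn_gene, mx_gene = trna_size_range([reference_annotations[0]])
        assert (mn, mx, mn_gene, mx_gene) == (53, 65, "trnW", "trnS1")

    def test_single_trna(self):
        ann = parse_gene_table("trnA 1 60", chromosome_length=100)
        assert trna_size_range([ann])[:2] == (60, 60)

    def test_no_trnas_raises(self):
        ann = parse_gene_table("cox1 1 90", chromosome_length=100)
        with pytest.raises(ValueError, match="no tRNA"):
            trna_size_range([ann])
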