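"""Region classification, codon-level consequences, and score attachment."""

import numpy as np
import pytest

from noncodnm import annotate as ann
from noncodnm.caller import DnmCall, TrioVariantRecord
from noncodnm.genemodel import GeneModel, GeneSet


def _rec(chrom="chr1", pos=1, ref="A", alt="G"):
    return TrioVariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        child_gt="0/1", mother_gt="0/0", father_gt="0/0",
        child_ad_ref=15, child_ad_alt=15, child_dp=30, mother_dp=30,
        father_dp=30, child_gq=60, mother_gq=60, father_gq=60,
    )


class TestRegionClassification:
    # toy_gene: tx [2000, 3800), exons [2000,2300)+[3300,3800),
    # CDS [2100, 3598), '+' strand, 1 kb flanks
    @pytest.mark.parametrize(
        "pos0, expected",
        [
            (2150, ("TOY1", "exonic")),       # inside CDS
            (2301, ("TOY1", "splicing")),     # 2nd intronic base past exon 1
            (3298, ("TOY1", "splicing")),     # 2 bp before exon 2
            (2050, ("TOY1", "UTR5")),
            (3700, ("TOY1", "UTR3")),
            (2800, ("TOY1", "intronic")),
            (1500, ("TOY1", "upstream")),     # within the 1 kb flank
            (3900, ("TOY1", "downstream")),
            (7100, ("TOYNC", "ncRNA_exonic")),
            (7201, ("TOYNC", "ncRNA_splicing")),
            (7400, ("TOYNC", "ncRNA_intronic")),
            (500, (None, "intergenic")),      # outside every footprint
        ],
    )
    def test_class_assignment(self, toy_genes, pos0, expected):
        assert ann.classify_region("chr1", pos0 + 1, toy_genes) == expected

    def test_third_intron_base_is_intronic_not_splicing(self, toy_genes):
        assert ann.classify_region("chr1", 2303, toy_genes) == \
            ("TOY1", "intronic")

    def test_out_of_bounds_rejected(self, toy_genes):
        with pytest.raises(ValueError):
            ann.classify_region("chr1", 20_001, toy_genes,
                                chrom_lengths={"chr1": 20_000})

    def test_reverse_strand_utr_orientation(self):
        g = GeneModel(gene_id="REV", chrom="chr1", strand="-",
                      tx_start=2000, tx_end=3800,
                      exons=[(2000, 2300), (3300, 3800)],
                      cds_start=2100, cds_end=3598)
        genes = GeneSet([g])
        # left of CDS is 3' on the minus strand
        assert ann.classify_region("chr1", 2051, genes) == ("REV", "UTR3")
        assert ann.classify_region("chr1", 3701, genes) == ("REV", "UTR5")
        assert ann.classify_region("chr1", 1501, genes) == ("REV", "downstream")

    def test_brute_force_membership_oracle(self, small_cohort):
        """classify_region agrees with naive per-position interval checks."""
        genes = small_cohort.genes
        rng = np.random.default_rng(11)
        chroms = list(small_cohort.reference.chrom_lengths)
        n_checked = 0
        for chrom in chroms:
            length = small_cohort.reference.chrom_lengths[chrom]
            for pos0 in rng.integers(0, length, 5000):
                gid, cls = ann.classify_region(chrom, int(pos0) + 1, genes)
                naive = _naive_classify(chrom, int(pos0), genes)
                assert (gid, cls) == naive, f"{chrom}:{pos0}"
                n_checked += 1
        assert n_checked >= 10_000

    def test_every_call_has_exactly_one_class(self, small_dnms):
        assert small_dnms["region_class"].isin(ann.REGION_PRECEDENCE).all()
        counts = small_dnms["region_class"].value_counts()
        assert counts.sum() == len(small_dnms)


def _naive_classify(chrom, pos0, genes):
    """Independent re-derivation of the precedence rules, interval by interval."""
    best = None
    for g in genes.by_chrom.get(chrom, []):
        if not (g.footprint_start <= pos0 < g.footprint_end):
            continue
        in_exon = any(s <= pos0 < e for s, e in g.exons)
        in_cds = any(s <= pos0 < e for s, e in g.cds)
        in_splice = any(
            (s - 2 <= pos0 < s and i > 0) or (e <= pos0 < e + 2 and i < len(g.exons) - 1)
            for i, (s, e) in enumerate(g.exons)
        ) and not in_exon
        if g.is_coding:
            if in_cds:
                cls = "exonic"
            elif in_splice:
                cls = "splicing"
            elif in_exon:
                left = pos0 < g.cds_start
                cls = ("UTR5" if left == (g.strand == "+") else "UTR3")
            elif g.tx_start <= pos0 < g.tx_end:
                cls = "intronic"
            elif pos0 < g.tx_start:
                cls = "upstream" if g.strand == "+" else "downstream"
            else:
                cls = "downstream" if g.strand == "+" else "upstream"
        else:
            if in_exon:
                cls = "ncRNA_exonic"
            elif in_splice:
                cls = "ncRNA_splicing"
            elif g.tx_start <= pos0 < g.tx_end:
                cls = "ncRNA_intronic"
            elif pos0 < g.tx_start:
                cls = "upstream" if g.strand == "+" else "downstream"
            else:
                cls = "downstream" if g.strand == "+" else "upstream"
        key = (ann.REGION_PRECEDENCE.index(cls), g.gene_id)
        if best is None or key < best[0]:
            best = (key, (g.gene_id, cls))
    return best[1] if best else (None, "intergenic")


class TestNearestGene:
    def test_minimum_distance_and_tie_break(self):
        a = GeneModel(gene_id="A", chrom="chr1", strand="+", tx_start=1000,
                      tx_end=2000, exons=[(1000, 2000)], cds_start=1000,
                      cds_end=1999, flank=100)
        b = GeneModel(gene_id="B", chrom="chr1", strand="+", tx_start=5000,
                      tx_end=6000, exons=[(5000, 6000)], cds_start=5000,
                      cds_end=5999, flank=100)
        genes = GeneSet([a, b])
        assert ann.assign_nearest_gene("chr1", 2500, genes) == "A"
        assert ann.assign_nearest_gene("chr1", 4500, genes) == "B"
        # exact tie at the midpoint -> lexicographically smaller id
        mid0 = (2100 + 4900 - 1) // 2
        assert ann.assign_nearest_gene("chr1", mid0 + 1, genes) == "A"

    def test_inside_footprint_rejected(self, toy_genes):
        with pytest.raises(ValueError):
            ann.assign_nearest_gene("chr1", 2500, toy_genes)

    def test_no_genes_on_chromosome(self, toy_genes):
        assert ann.assign_nearest_gene("chr9", 100, toy_genes) is None


class TestCodingConsequence:
    @pytest.fixture
    def seq_and_gene(self):
        # 60 bp chromosome; CDS = single exon [10, 31): ATG AAA TAC CCG TAA ...
        cds = "ATGAAATACCCGTAA"
        seq = "G" * 10 + cds + "G" * 35
        g = GeneModel(gene_id="C1", chrom="chr1", strand="+", tx_start=5,
                      tx_end=40, exons=[(5, 40)], cds_start=10, cds_end=25)
        return seq, g

    def test_genetic_code_calls(self, seq_and_gene):
        seq, g = seq_and_gene
        # codon 2 = AAA (Lys): third base A->G gives AAG (Lys), synonymous
        assert ann.coding_consequence(16, "A", "G", g, seq, "exonic") == \
            ("synonymous", False)
        # first base A->G gives GAA (Glu), missense
        assert ann.coding_consequence(14, "A", "G", g, seq, "exonic") == \
            ("missense", False)
        # codon 3 = TAC (Tyr): C->A gives TAA (stop), stopgain and LGD
        assert ann.coding_consequence(19, "C", "A", g, seq, "exonic") == \
            ("stopgain", True)
        # start codon ATG disrupted
        assert ann.coding_consequence(11, "A", "C", g, seq, "exonic") == \
            ("startloss", True)
        # stop codon TAA -> CAA: stoploss
        assert ann.coding_consequence(23, "T", "C", g, seq, "exonic") == \
            ("stoploss", True)

    def test_indel_frame_logic(self, seq_and_gene):
        seq, g = seq_and_gene
        assert ann.coding_consequence(14, "A", "AG", g, seq, "exonic") == \
            ("frameshift_insertion", True)
        assert ann.coding_consequence(14, "AAA", "A", g, seq, "exonic") == \
            ("frameshift_deletion", True)
        assert ann.coding_consequence(14, "AAAT", "A", g, seq, "exonic") == \
            ("nonframeshift_indel", False)

    def test_splicing_region_is_lgd(self, seq_and_gene):
        seq, g = seq_and_gene
        assert ann.coding_consequence(14, "A", "G", g, seq, "splicing") == \
            ("splicing", True)

    def test_reverse_strand_metamorphic(self, seq_and_gene):
        """Consequences on the reverse-complemented construct are identical."""
        from Bio.Seq import Seq

        seq, g = seq_and_gene
        L = len(seq)
        rc = str(Seq(seq).reverse_complement())
        g_rc = GeneModel(gene_id="C1R", chrom="chr1", strand="-",
                         tx_start=L - 40, tx_end=L - 5,
                         exons=[(L - 40, L - 5)],
                         cds_start=L - 25, cds_end=L - 10)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for pos, ref, alt in [(16, "A", "G"), (14, "A", "G"), (19, "C", "A"),
                              (11, "A", "C"), (23, "T", "C")]:
            fwd = ann.coding_consequence(pos, ref, alt, g, seq, "exonic")
            pos_rc = L - pos + 1
            rev = ann.coding_consequence(pos_rc, comp[ref], comp[alt],
                                         g_rc, rc, "exonic")
            assert fwd == rev

    def test_cds_not_multiple_of_three_flagged_other(self):
        seq = "G" * 10 + "ATGAAAT" + "G" * 20
        g = GeneModel(gene_id="BAD", chrom="chr1", strand="+", tx_start=5,
                      tx_end=30, exons=[(5, 30)], cds_start=10, cds_end=17)
        assert ann.coding_consequence(12, "T", "C", g, seq, "exonic") == \
            ("other", False)


class TestScores:
    class _FixedScores:
        def __init__(self, cadd, fathmm, spliceai):
            self.vals = (cadd, fathmm, spliceai)

        def at(self, chrom, pos1):
            return self.vals

    @pytest.mark.parametrize(
        "cadd, fathmm, spliceai, flags",
        [
            (15.0, 0.5, 0.8, dict(cadd15=True, fathmm_patho=False,
                                  spliceai_high=True)),
            (14.99, 0.51, 0.79, dict(cadd15=False, fathmm_patho=True,
                                     spliceai_high=False)),
            (None, None, None, dict(cadd15=False, fathmm_patho=False,
                                    spliceai_high=False)),
        ],
    )
    def test_threshold_semantics(self, cadd, fathmm, spliceai, flags):
        call = DnmCall(record=_rec(), child_id="k", cohort="case")
        ann.attach_scores([call], self._FixedScores(cadd, fathmm, spliceai))
        assert ann.score_flags(call) == flags
        assert call.cadd == cadd  # missing stays missing, never imputed


class TestNoncodingFunctionalLength:
    def test_brute_force_recount(self, small_cohort):
        scores = small_cohort.scores
        for g in list(small_cohort.genes)[:5]:
            manual = 0
            for s, e in g.noncoding_footprint:
                for p in range(s, e):
                    if scores.cadd(g.chrom, np.int64(p)) >= 15.0:
                        manual += 1
            assert ann.compute_noncoding_functional_length(g, scores) == manual
            assert g.noncoding_functional_length == manual

    def test_gap_in_coverage_raises(self, toy_gene):
        class Gappy:
            def cadd_range(self, chrom, s, e):
                return np.full(e - s, np.nan)

        with pytest.raises(ValueError, match="does not cover"):
            ann.compute_noncoding_functional_length(toy_gene, Gappy())

    def test_footprint_partition(self, small_cohort):
        """coding span + noncoding footprint lengths tile the footprint."""
        from noncodnm import intervals as iv

        for g in small_cohort.genes:
            coding_span = iv.total_length(g.coding_span) if g.coding_span else 0
            assert coding_span + g.noncoding_footprint_length == \
                g.footprint_length
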