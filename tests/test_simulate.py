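"""Synthetic cohort generator: determinism, structure, planted statistics."""

import numpy as np
import pytest

from noncodnm import intervals as iv
from noncodnm.genemodel import read_gene_table, write_gene_table
from noncodnm.pipeline import build_cohort
from noncodnm.simulate import (
    SimulationConfig,
    generate_gene_models,
    generate_gnocchi_bins,
    generate_mutation_rate_table,
    generate_reference,
    generate_site_scores,
    simulate_trio_cohort,
)


class TestReference:
    def test_length_composition_and_determinism(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length=100_000)
        ref = generate_reference(cfg)
        seq = ref.sequence("chr1")
        assert len(seq) == 100_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.3 < gc < 0.7
        ref2 = generate_reference(cfg)
        assert ref2.sequence("chr1") == seq

    def test_different_seeds_differ(self):
        cfg1 = SimulationConfig(seed=1, n_chromosomes=1, chrom_length=100_000)
        cfg2 = SimulationConfig(seed=2, n_chromosomes=1, chrom_length=100_000)
        a = generate_reference(cfg1).arrays["chr1"]
        b = generate_reference(cfg2).arrays["chr1"]
        assert (a != b).mean() > 0.01

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(chrom_length=5000)


class TestGeneModels:
    def test_structure_constraints(self, small_cohort):
        genes = list(small_cohort.genes)
        assert len(genes) == 25
        for g in genes:
            assert len(g.exons) >= 2
            assert g.exons == sorted(g.exons)
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                assert e1 < s2  # disjoint
            assert g.tx_start <= g.exons[0][0] and g.exons[-1][1] <= g.tx_end
            if g.is_coding:
                assert g.coding_length % 3 == 0

    def test_footprints_do_not_overlap(self, small_cohort):
        for chrom, genes in small_cohort.genes.by_chrom.items():
            for a, b in zip(genes, genes[1:]):
                assert a.footprint_end <= b.footprint_start

    def test_total_cds_equals_sum_of_coding_lengths(self, small_cohort):
        total = 0
        for chrom, chrom_genes in small_cohort.genes.by_chrom.items():
            all_cds = [ivl for g in chrom_genes for ivl in g.cds]
            total += iv.total_length(all_cds) if all_cds else 0
        assert total == sum(g.coding_length for g in small_cohort.genes)

    def test_infeasible_packing_reported(self):
        cfg = SimulationConfig(n_genes=500, n_chromosomes=1, chrom_length=50_000)
        ref = generate_reference(cfg)
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_gene_models(cfg, ref)

    def test_gene_table_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "genes.tsv"
        write_gene_table(small_cohort.genes, path)
        back = read_gene_table(path)
        assert len(back) == len(small_cohort.genes)
        for g in small_cohort.genes:
            h = back[g.gene_id]
            assert (h.exons, h.cds, h.strand) == (g.exons, g.cds, g.strand)
            assert h.noncoding_functional_length == g.noncoding_functional_length


class TestRateTable:
    def test_length_correlation_and_probability_sanity(self):
        cfg = SimulationConfig(seed=7, n_genes=100, n_chromosomes=4,
                               chrom_length=1_000_000)
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        rates = generate_mutation_rate_table(genes, cfg)
        corr = np.corrcoef(rates["rate_length"], rates["p_total"])[0, 1]
        assert corr >= 0.8
        assert (rates["p_total"] > 0).all()
        assert rates["p_total"].sum() < 1
        assert (rates["p_missense"] + rates["p_lgd"] <= rates["p_total"]).all()


class TestScoreTrack:
    def test_cadd_tail_fraction(self):
        cfg = SimulationConfig(seed=3, n_chromosomes=1, chrom_length=1_000_000)
        scores = generate_site_scores(cfg, generate_reference(cfg))
        frac = (scores.cadd_range("chr1", 0, 1_000_000) >= 15.0).mean()
        assert 0.015 <= frac <= 0.021

    def test_reproducible_and_bounded(self):
        cfg = SimulationConfig(seed=3, n_chromosomes=1, chrom_length=20_000)
        ref = generate_reference(cfg)
        a = generate_site_scores(cfg, ref).cadd_range("chr1", 0, 20_000)
        b = generate_site_scores(cfg, ref).cadd_range("chr1", 0, 20_000)
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() < 45
        sp = generate_site_scores(cfg, ref).spliceai("chr1", np.arange(20_000))
        fa = generate_site_scores(cfg, ref).fathmm("chr1", np.arange(20_000))
        assert 0 <= sp.min() and sp.max() <= 1 and 0 <= fa.min() and fa.max() <= 1

    def test_score_table_round_trip(self, tmp_path):
        from noncodnm.simulate import TableScores

        cfg = SimulationConfig(seed=5, n_chromosomes=1, chrom_length=10_000)
        ref = generate_reference(cfg)
        track = generate_site_scores(cfg, ref)
        path = tmp_path / "scores.tsv"
        track.write_table(path, regions={"chr1": [(100, 300)]})
        table = TableScores.from_file(path)
        c, f, s = table.at("chr1", 150)
        ch, fh, sh = track.at("chr1", 150)
        assert c == pytest.approx(ch, abs=5e-4)
        assert table.at("chr1", 5000) == (None, None, None)


class TestBins:
    def test_tiling_and_beta_normalization(self, small_bins, small_config):
        n_expected = (small_config.chrom_length // 1000) * small_config.n_chromosomes
        assert len(small_bins) == n_expected
        assert abs(small_bins["beta"].mean() - 1.0) < 1e-9
        assert (small_bins["expected_rare"] >= 0).all()

    def test_coding_overlap_flagging(self, small_bins, small_cohort):
        for g in small_cohort.genes:
            if not g.is_coding:
                continue
            s, e = g.cds[0]
            row = small_bins[(small_bins["chrom"] == g.chrom)
                             & (small_bins["start"] == (s // 1000) * 1000)]
            assert row["region_flag"].iloc[0] == "coding_overlap"

    def test_short_chromosome_rejected(self, small_config):
        class FakeRef:
            chrom_lengths = {"chr1": 500}

        from noncodnm.genemodel import GeneSet

        with pytest.raises(ValueError, match="shorter"):
            generate_gnocchi_bins(small_config, FakeRef(), GeneSet([]))


class TestCohort:
    def test_poisson_dnm_count_mean(self):
        cfg = SimulationConfig(seed=11, n_genes=15, n_case_trios=150,
                               n_control_trios=1, chrom_length=300_000,
                               genomewide_dnm_rate=90.0,
                               background_hets_per_child=0)
        cohort = build_cohort(cfg)
        counts = cohort.truth[cohort.truth["kind"] == "clean"] \
            .groupby("child_id").size()
        se = np.sqrt(90.0 / 150)
        assert abs(counts.mean() - 90.0) < 3 * se

    def test_truth_matches_vcf_child_carriers(self, small_cohort):
        """Planted truth rows equal child-carrying records across families."""
        n_records = sum(
            sum(1 for r in fam.records if "1" in r["child_gt"])
            for fam in small_cohort.families
        )
        child_carrier_truth = small_cohort.truth  # backgrounds may be 0/1 too
        planted = child_carrier_truth[
            child_carrier_truth["kind"].isin(["clean", "decoy", "background"])]
        assert n_records == len(planted)

    def test_decoys_present_and_labeled(self, small_cohort):
        decoys = small_cohort.truth[small_cohort.truth["kind"] == "decoy"]
        assert len(decoys) > 0
        assert set(decoys["decoy_target"]) <= {
            "ad_alt", "child_gq", "parent_gq", "parent_dp", "pop_af",
            "mappability", "ab", "blacklist"}

    def test_null_case_control_balance(self):
        """No enrichment, equal arms: aggregate counts split ~binomially."""
        from scipy import stats as sps

        cfg = SimulationConfig(seed=13, n_genes=20, n_case_trios=40,
                               n_control_trios=40, chrom_length=300_000,
                               genomewide_dnm_rate=40.0,
                               background_hets_per_child=0)
        cohort = build_cohort(cfg)
        genic = cohort.truth[(cohort.truth["kind"] == "clean")
                             & (cohort.truth["region"] == "genic")]
        n_case = (genic["cohort"] == "case").sum()
        p = sps.binomtest(int(n_case), len(genic), 0.5).pvalue
        assert p > 1e-3

    def test_unknown_enrichment_gene_rejected(self, small_config, small_cohort):
        cfg = SimulationConfig(seed=1, enrichment_spec={"NOPE": 10.0})
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        rates = generate_mutation_rate_table(genes, cfg)
        with pytest.raises(ValueError, match="unknown gene ids"):
            simulate_trio_cohort(cfg, ref, genes, rates)

    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_genes=8, n_case_trios=3,
                               n_control_trios=3, chrom_length=150_000,
                               n_chromosomes=1, decoys_per_child=0.5)
        outs = []
        for run in ("a", "b"):
            cohort = build_cohort(cfg)
            d = tmp_path / run
            cohort.write_vcfs(d)
            cohort.reference.write_fasta(d / "ref.fa")
            cohort.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
            outs.append({
                p.name: p.read_bytes() for p in sorted(d.rglob("*")) if p.is_file()
            })
        assert outs[0] == outs[1]
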