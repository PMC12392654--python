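"""Trio DNM detection, the eight hard filters, and the 100 bp collapse."""

import itertools
import shutil
import subprocess

import pytest

from noncodnm.caller import (
    DnmCall,
    FilterThresholds,
    MappabilityMask,
    TrioVariantRecord,
    allele_balance,
    apply_dnm_filters,
    collapse_nearby,
    detect_candidate_dnms,
    left_align,
    normalize_and_split,
)


def _record(**kw) -> TrioVariantRecord:
    base = dict(
        chrom="chr1", pos=100, ref="A", alt="G",
        child_gt="0/1", mother_gt="0/0", father_gt="0/0",
        child_ad_ref=15, child_ad_alt=15, child_dp=30,
        mother_dp=30, father_dp=30,
        child_gq=60, mother_gq=60, father_gq=60, pop_af=None,
    )
    base.update(kw)
    return TrioVariantRecord(**base)


class TestNormalization:
    def test_multiallelic_split(self):
        raw = [dict(chrom="chr1", pos=100, ref="AT", alts=["A", "ATT"],
                    child_gt="1/2", mother_gt="0/0", father_gt="0/0",
                    child_ad=[2, 10, 9], child_dp=21, mother_dp=30,
                    father_dp=30, child_gq=50, mother_gq=50, father_gq=50)]
        out = normalize_and_split(raw)
        assert len(out) == 2
        assert all(r.pos == 100 for r in out)
        assert {(r.ref, r.alt) for r in out} == {("AT", "A"), ("AT", "ATT")}
        assert out[0].child_ad_alt == 10 and out[1].child_ad_alt == 9
        # genotype re-expressed per alt: carrier of each allele is het
        assert out[0].child_gt == "0/1" and out[1].child_gt == "0/1"

    def test_already_normalized_snv_unchanged(self):
        seq = "ACGTACGTAC"
        assert left_align(5, "A", "G", seq) == (5, "A", "G")

    def test_homopolymer_deletion_left_shifts(self):
        #        123456789
        seq = "GTAAAAAC"
        # deleting one A represented at the right end of the run
        pos, ref, alt = left_align(6, "AA", "A", seq)
        assert (pos, ref, alt) == (2, "TA", "T")

    def test_exhaustive_left_shift_oracle(self):
        """All representations of the same indel normalize identically."""
        seq = "GCATTTTTTGCA"  # T homopolymer spans 1-based positions 4..9
        reps = [(i, seq[i - 1: i + 1], seq[i - 1]) for i in range(3, 9)]
        normalized = {left_align(p, r, a, seq) for p, r, a in reps}
        assert len(normalized) == 1

    @pytest.mark.skipif(shutil.which("bcftools") is None,
                        reason="bcftools unavailable")
    def test_against_bcftools_norm(self, tmp_path):
        seq = "GCATTTTTTGCAAACGGG"
        (tmp_path / "ref.fa").write_text(">chr1\n" + seq + "\n")
        vcf = "\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=18>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
            "chr1\t8\tv1\tTT\tT\t.\t.\t.",
            "chr1\t13\tv2\tAA\tA\t.\t.\t.",
            "chr1\t5\tv3\tT\tTTT\t.\t.\t.",
        ]) + "\n"
        (tmp_path / "in.vcf").write_text(vcf)
        out = subprocess.run(
            ["bcftools", "norm", "-f", str(tmp_path / "ref.fa"),
             str(tmp_path / "in.vcf")],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = {}
        for line in out.splitlines():
            if line.startswith("#"):
                continue
            f = line.split("\t")
            expected[f[2]] = (int(f[1]), f[3], f[4])
        assert left_align(8, "TT", "T", seq) == expected["v1"]
        assert left_align(13, "AA", "A", seq) == expected["v2"]
        assert left_align(5, "T", "TTT", seq) == expected["v3"]

    def test_symbolic_and_star_alts_dropped(self):
        raw = [dict(chrom="chr1", pos=10, ref="A", alts=["*", "<DEL>", "C"],
                    child_gt="0/3", mother_gt="0/0", father_gt="0/0",
                    child_ad=[10, 0, 0, 12], child_dp=22, mother_dp=30,
                    father_dp=30, child_gq=50, mother_gq=50, father_gq=50)]
        out = normalize_and_split(raw)
        assert len(out) == 1 and out[0].alt == "C"


class TestCandidateDetection:
    def test_mendelian_candidate_definition(self):
        recs = [
            _record(),  # child het, parents hom-ref -> candidate
            _record(pos=200, father_gt="0/1"),  # allele in a parent
            _record(pos=300, child_gt="1/1"),  # implausible de novo
            _record(pos=400, mother_gt="./."),  # missing parent
            _record(pos=500, child_gt="0/0"),  # child not a carrier
        ]
        cands, excluded = detect_candidate_dnms(recs, "kid1", "case")
        assert [c.record.pos for c in cands] == [100]
        reasons = {c.record.pos: c.fail_reasons for c in excluded}
        assert reasons[200] == {"parent_carrier"}
        assert reasons[300] == {"child_hom_alt"}
        assert reasons[400] == {"parent_missing"}
        assert reasons[500] == {"child_not_carrier"}


class TestAlleleBalance:
    @pytest.mark.parametrize("ref, alt, ab", [(10, 10, 0.5), (30, 10, 0.25),
                                              (3, 9, 0.75)])
    def test_fraction(self, ref, alt, ab):
        assert allele_balance(ref, alt) == pytest.approx(ab)

    def test_zero_depth_undefined(self):
        with pytest.raises(ValueError):
            allele_balance(0, 0)


class TestFilters:
    def _run(self, rec, **kw):
        call = DnmCall(record=rec, child_id="kid", cohort="case")
        apply_dnm_filters([call], **kw)
        return call

    def test_boundary_semantics(self):
        # AD 5 < 6 fails; AB = 5/20 = 0.25 is inclusive and passes
        c = self._run(_record(child_ad_ref=15, child_ad_alt=5, child_dp=20))
        assert c.fail_reasons == {"ad_alt"}
        # parent DP exactly 8 fails the strict > 8 rule
        c = self._run(_record(mother_dp=8))
        assert c.fail_reasons == {"parent_dp"}
        # AD 6 with AB exactly 0.25 passes everything
        c = self._run(_record(child_ad_ref=18, child_ad_alt=6, child_dp=24))
        assert c.passed
        # AB just outside the closed range fails
        c = self._run(_record(child_ad_ref=25, child_ad_alt=6, child_dp=31))
        assert c.fail_reasons == {"ab"}

    def test_all_violations_accumulate(self):
        c = self._run(_record(child_ad_alt=2, child_ad_ref=28, child_gq=10,
                              mother_gq=5, father_dp=4, pop_af=0.5))
        assert c.fail_reasons == {"ad_alt", "child_gq", "parent_gq",
                                  "parent_dp", "pop_af", "ab"}

    def test_missing_af_passes_frequency_filter(self):
        assert self._run(_record(pop_af=None)).passed
        assert self._run(_record(pop_af=0.0009)).passed
        assert not self._run(_record(pop_af=0.001)).passed

    def test_mask_lookup(self):
        mask = MappabilityMask({"chr1": [(90, 110)]})
        assert not self._run(_record(pos=100), mask=mask).passed
        assert self._run(_record(pos=111), mask=mask).passed

    def test_malformed_mask_rejected(self):
        with pytest.raises(ValueError):
            MappabilityMask({"chr1": [(100, 100)]})

    def test_partition_and_idempotence(self, small_cohort, small_calls):
        statuses = {c.filter_status for c in small_calls}
        assert statuses <= {"pass", "fail", "collapsed"}
        n_pass = sum(c.filter_status != "fail" for c in small_calls)
        n_fail = sum(c.filter_status == "fail" for c in small_calls)
        assert n_pass + n_fail == len(small_calls)
        passed = [c for c in small_calls if c.passed]
        apply_dnm_filters(passed, FilterThresholds(), small_cohort.mask,
                          small_cohort.af_table)
        assert all(c.passed for c in passed)

    def test_loosening_thresholds_never_reduces_pass_count(self, small_cohort):
        from noncodnm.pipeline import call_cohort

        base = FilterThresholds()
        looser = [
            FilterThresholds(min_child_ad_alt=4),
            FilterThresholds(min_child_gq=10),
            FilterThresholds(min_parent_gq=5),
            FilterThresholds(min_parent_dp_exclusive=2),
            FilterThresholds(max_pop_af=0.5),
            FilterThresholds(ab_low=0.1, ab_high=0.9),
        ]
        n_base = sum(c.filter_status != "fail"
                     for c in call_cohort(small_cohort, base))
        for th in looser:
            n = sum(c.filter_status != "fail"
                    for c in call_cohort(small_cohort, th))
            assert n >= n_base


class TestCollapse:
    def _call(self, pos, severity, gene="G1", child="kid"):
        c = DnmCall(record=_record(pos=pos), child_id=child, cohort="case")
        c.gene_id = gene
        c.severity_rank = severity
        return c

    def test_keeps_most_severe_within_window(self):
        lgd, intronic = self._call(1000, 9), self._call(1050, 4)
        kept = collapse_nearby([lgd, intronic], window=100)
        assert kept == [lgd]

    def test_outside_window_keeps_both(self):
        a, b = self._call(1000, 8), self._call(1151, 8)
        assert len(collapse_nearby([a, b], window=100)) == 2

    def test_transitive_chain_collapses_to_one(self):
        a = self._call(1000, 4)   # intronic
        b = self._call(1080, 8)   # missense
        c = self._call(1160, 4)   # intronic; a-c are 160 bp apart
        kept = collapse_nearby([a, b, c], window=100)
        assert kept == [b]

    def test_brute_force_clustering_oracle(self):
        """Single-linkage clusters match an exhaustive pairwise closure."""
        import numpy as np

        rng = np.random.default_rng(7)
        for _ in range(20):
            pos = sorted(rng.integers(0, 2000, 15).tolist())
            sev = rng.integers(1, 10, 15).tolist()
            calls = [self._call(int(p) + 1, int(s))
                     for p, s in zip(pos, sev)]
            kept = collapse_nearby(calls, window=100)
            # oracle: transitive closure of the <=100 bp relation
            parent = list(range(len(calls)))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i, j in itertools.combinations(range(len(calls)), 2):
                if abs(calls[i].record.pos - calls[j].record.pos) <= 100:
                    parent[find(i)] = find(j)
            clusters = {}
            for i, c in enumerate(calls):
                clusters.setdefault(find(i), []).append(c)
            expected = {
                id(min(cl, key=lambda c: (-c.severity_rank, c.record.pos)))
                for cl in clusters.values()
            }
            assert {id(c) for c in kept} == expected

    def test_unannotated_pass_through(self):
        c = DnmCall(record=_record(), child_id="kid", cohort="case")
        assert collapse_nearby([c]) == [c]

    def test_different_genes_not_collapsed(self):
        a = self._call(1000, 9, gene="G1")
        b = self._call(1010, 4, gene="G2")
        assert len(collapse_nearby([a, b])) == 2


class TestThresholdValidation:
    def test_invalid_ab_range_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(ab_low=0.8, ab_high=0.2)
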