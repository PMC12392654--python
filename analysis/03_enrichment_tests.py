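#!/usr/bin/env python
"""Per-gene case-only enrichment tests on the demo cohort.

Runs the point-based tests (coding, missense, LGD, CADD>=15 noncoding genic
and intergenic) and the segment-based tests (genic and intergenic 1 kb bins
with beta-scaled backgrounds), writes the result tables, and reports whether
the genes planted with 8-fold enrichment surface at the top of the ranking.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd
from common import ANALYSIS_DIR, ENRICHED_GENES, N_CASE, N_CONTROL, STUDY_DIR

from noncodnm.genemodel import read_gene_table
from noncodnm.point_test import CohortConfig, run_point_tests
from noncodnm.segment_test import run_segment_test


def main() -> None:
    dnms = pd.read_csv(ANALYSIS_DIR / "annotated_dnms.tsv", sep="\t",
                       dtype={"chrom": str})
    genes = read_gene_table(STUDY_DIR / "genes.tsv")
    rates = pd.read_csv(STUDY_DIR / "rates.tsv", sep="\t")
    bins = pd.read_csv(STUDY_DIR / "bins.tsv", sep="\t", dtype={"chrom": str})
    cohort = CohortConfig("demo", N_CASE, N_CONTROL)

    point = run_point_tests(dnms, rates, genes, cohort)
    point.to_csv(ANALYSIS_DIR / "point_tests.tsv", sep="\t", index=False)

    segment = pd.concat([
        run_segment_test(dnms, bins, genes, mode=mode)
        for mode in ("genic", "intergenic")
    ])
    segment.to_csv(ANALYSIS_DIR / "segment_tests.tsv", sep="\t", index=False)

    coding = point[point["test_family"] == "coding"].dropna(subset=["p_value"])
    top = coding.nsmallest(5, "p_value")
    print("top 5 genes, coding point test (observed/expected, p):")
    for row in top.itertuples(index=False):
        mark = " <- planted 8x" if row.gene_id in ENRICHED_GENES else ""
        print(f"  {row.gene_id}: {row.observed}/{row.expected:.2f}, "
              f"p={row.p_value:.2e}{mark}")
    recovered = sum(g in set(top["gene_id"]) for g in ENRICHED_GENES)
    print(f"planted genes in coding top 5: {recovered}/{len(ENRICHED_GENES)}")

    nc = point[point["test_family"] == "noncoding_genic"].dropna(
        subset=["p_value"])
    top_nc = nc.nsmallest(3, "p_value")
    print("top 3 genes, CADD>=15 noncoding point test:")
    for row in top_nc.itertuples(index=False):
        mark = " <- planted 8x" if row.gene_id in ENRICHED_GENES else ""
        print(f"  {row.gene_id}: {row.observed}/{row.expected:.2f}, "
              f"p={row.p_value:.2e}{mark}")

    seg_genic = segment[segment["test_family"] == "segment_genic"]
    top_seg = seg_genic.nsmallest(3, "p_value")
    print("top 3 genes, genic segment test:")
    for row in top_seg.itertuples(index=False):
        mark = " <- planted 8x" if row.gene_id in ENRICHED_GENES else ""
        print(f"  {row.gene_id}: {row.observed}/{row.expected:.2f} "
              f"over {row.n_bins} bins, p={row.p_value:.2e}{mark}")


if __name__ == "__main__":
    main()
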