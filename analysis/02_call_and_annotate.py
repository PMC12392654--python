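#!/usr/bin/env python
"""Call de novo mutations from the demo VCFs and annotate them.

Reads results/demo_study/ (written by 01_simulate_cohort.py), runs the
Mendelian candidate detection and the eight hard filters on every family,
annotates region class / consequence / functional scores, applies the
within-gene 100 bp collapse, and writes the annotated DNM table plus a
per-filter exclusion accounting to results/demo_analysis/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from collections import Counter

import pandas as pd
from common import ANALYSIS_DIR, STUDY_DIR

from noncodnm.annotate import annotate_calls
from noncodnm.caller import (
    FilterThresholds,
    MappabilityMask,
    apply_blacklist,
    apply_dnm_filters,
    calls_to_table,
    collapse_nearby,
    detect_candidate_dnms,
    load_af_table,
    normalize_and_split,
    read_family_vcf,
)
from noncodnm.genemodel import read_gene_table
from noncodnm.simulate import HashedScoreTrack
from common import SEED


def main() -> None:
    from pyfaidx import Fasta

    genes = read_gene_table(STUDY_DIR / "genes.tsv")
    seqs = {name: str(rec[:]) for name, rec in
            Fasta(str(STUDY_DIR / "reference.fa")).items()}
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    scores = HashedScoreTrack(SEED, chrom_lengths)
    mask = MappabilityMask.from_bed(STUDY_DIR / "mask.bed")
    af = load_af_table(STUDY_DIR / "af.tsv")
    thresholds = FilterThresholds()

    calls = []
    vcfs = sorted((STUDY_DIR / "vcf").glob("*.vcf"))
    for path in vcfs:
        child, records = read_family_vcf(path)
        cohort_label = "case" if child.startswith("case") else "control"
        normalized = normalize_and_split(records, seqs)
        candidates, _ = detect_candidate_dnms(normalized, child, cohort_label)
        apply_dnm_filters(candidates, thresholds, mask, af)
        calls.extend(candidates)
    annotate_calls(calls, genes, seqs, scores, chrom_lengths)
    apply_blacklist(calls, thresholds)
    passed = [c for c in calls if c.passed]
    kept = {id(c) for c in collapse_nearby(passed, thresholds.collapse_window_bp)}
    for c in passed:
        if id(c) not in kept:
            c.filter_status = "collapsed"

    table = calls_to_table(calls)
    ANALYSIS_DIR.mkdir(parents=True, exist_ok=True)
    table.to_csv(ANALYSIS_DIR / "annotated_dnms.tsv", sep="\t", index=False)

    reasons = Counter(
        r for rs in table.loc[table["filter_status"] == "fail", "fail_reasons"]
        for r in rs.split(";"))
    accounting = pd.DataFrame(sorted(reasons.items()),
                              columns=["filter", "n_excluded"])
    accounting.to_csv(ANALYSIS_DIR / "filter_accounting.tsv", sep="\t",
                      index=False)

    n = len(table)
    status = table["filter_status"].value_counts()
    print(f"{len(vcfs)} families -> {n} candidate DNMs")
    print(f"  pass {status.get('pass', 0)}, fail {status.get('fail', 0)}, "
          f"collapsed {status.get('collapsed', 0)}")
    print("  exclusions by filter:",
          ", ".join(f"{k}={v}" for k, v in sorted(reasons.items())))
    passed_df = table[table["filter_status"] == "pass"]
    print("  region classes of passing calls:")
    for cls, count in passed_df["region_class"].value_counts().items():
        print(f"    {cls:>15}: {count}")


if __name__ == "__main__":
    main()
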