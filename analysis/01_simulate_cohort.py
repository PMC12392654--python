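#!/usr/bin/env python
"""Generate the demo synthetic study: reference, gene models, rate table,
score track, 1 kb constraint bins, mappability mask, allele frequencies,
per-family trio VCFs, and the planted-DNM truth table.

Writes everything under results/demo_study/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SIM_CONFIG, STUDY_DIR

from noncodnm.genemodel import write_gene_table
from noncodnm.pipeline import build_cohort
from noncodnm.simulate import (
    SimulationConfig,
    generate_gnocchi_bins,
    write_mask_bed,
)


def main() -> None:
    cfg = SimulationConfig(**SIM_CONFIG)
    cohort = build_cohort(cfg)
    STUDY_DIR.mkdir(parents=True, exist_ok=True)
    cohort.reference.write_fasta(STUDY_DIR / "reference.fa")
    write_gene_table(cohort.genes, STUDY_DIR / "genes.tsv")
    cohort.rates.to_csv(STUDY_DIR / "rates.tsv", sep="\t", index=False)
    bins = generate_gnocchi_bins(cfg, cohort.reference, cohort.genes)
    bins.to_csv(STUDY_DIR / "bins.tsv", sep="\t", index=False)
    write_mask_bed(cohort.mask, STUDY_DIR / "mask.bed")
    cohort.write_af_table(STUDY_DIR / "af.tsv")
    cohort.truth.to_csv(STUDY_DIR / "truth.tsv", sep="\t", index=False)
    vcfs = cohort.write_vcfs(STUDY_DIR / "vcf")

    truth = cohort.truth
    clean = truth[truth["kind"] == "clean"]
    per_child = clean.groupby("child_id").size()
    print(f"study written to {STUDY_DIR}")
    print(f"  {len(cohort.genes)} genes on {cfg.n_chromosomes} chromosomes "
          f"({cfg.chrom_length:,} bp each); {len(bins)} 1 kb bins")
    print(f"  {len(vcfs)} family VCFs "
          f"({cfg.n_case_trios} case + {cfg.n_control_trios} control trios)")
    print(f"  planted DNMs per child: mean {per_child.mean():.1f} "
          f"(configured {cfg.genomewide_dnm_rate})")
    print(f"  decoys planted: {(truth['kind'] == 'decoy').sum()}, "
          f"background inherited hets: {(truth['kind'] == 'background').sum()}")


if __name__ == "__main__":
    main()
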