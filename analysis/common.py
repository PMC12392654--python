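"""Shared configuration for the demo analysis scripts.

A small self-contained synthetic study: two chromosomes, 40 genes, 60 case
and 60 control trios, with three genes given an 8-fold de novo mutation
enrichment in the case arm, engineered low-quality decoys, and two
blacklist-named genes (HLA*/MUC*) to exercise every filter.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "demo_study"
ANALYSIS_DIR = RESULTS / "demo_analysis"

SEED = 2025

ENRICHED_GENES = {"G0010": 8.0, "G0017": 8.0, "G0024": 8.0}

SIM_CONFIG = dict(
    seed=SEED,
    n_chromosomes=2,
    chrom_length=600_000,
    n_genes=40,
    n_case_trios=60,
    n_control_trios=60,
    genomewide_dnm_rate=90.0,
    enrichment_spec=ENRICHED_GENES,
    decoys_per_child=1.0,
    n_blacklist_genes=2,
)

N_CASE = SIM_CONFIG["n_case_trios"]
N_CONTROL = SIM_CONFIG["n_control_trios"]
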