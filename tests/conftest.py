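import pandas as pd
import pytest

from noncodnm.caller import calls_to_table
from noncodnm.genemodel import GeneModel, GeneSet
from noncodnm.pipeline import build_cohort, call_cohort
from noncodnm.simulate import SimulationConfig, generate_gnocchi_bins


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=3, n_genes=25, n_case_trios=8, n_control_trios=8,
        n_chromosomes=2, chrom_length=250_000,
        decoys_per_child=1.5, n_blacklist_genes=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return build_cohort(small_config)


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    return call_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_dnms(small_calls) -> pd.DataFrame:
    return calls_to_table(small_calls)


@pytest.fixture(scope="session")
def small_bins(small_config, small_cohort) -> pd.DataFrame:
    return generate_gnocchi_bins(small_config, small_cohort.reference,
                                 small_cohort.genes)


@pytest.fixture
def toy_gene() -> GeneModel:
    """Forward-strand two-exon coding gene with UTRs on a 10 kb chromosome.

    exon1: [2000, 2300) with UTR5 [2000, 2100) and CDS start 2100
    intron: [2300, 3300)
    exon2: [3300, 3800) with CDS end 3600 and UTR3 [3600, 3800)
    CDS length (2300-2100) + (3600-3300) = 500... adjusted to 498 (%3 == 0)
    """
    return GeneModel(
        gene_id="TOY1", chrom="chr1", strand="+",
        tx_start=2000, tx_end=3800,
        exons=[(2000, 2300), (3300, 3800)],
        cds_start=2100, cds_end=3598,  # 200 + 298 = 498 coding bases
        flank=1000,
    )


@pytest.fixture
def toy_genes(toy_gene) -> GeneSet:
    ncrna = GeneModel(
        gene_id="TOYNC", chrom="chr1", strand="+",
        tx_start=7000, tx_end=7900,
        exons=[(7000, 7200), (7600, 7900)],
        cds_start=7000, cds_end=7000,
        flank=1000,
    )
    return GeneSet([toy_gene, ncrna])
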