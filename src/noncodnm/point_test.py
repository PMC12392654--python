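"""Case-only point-based Poisson enrichment tests.

For coding DNMs the expected count per gene is the gene's de novo mutation
probability x n_trios x 2 (two autosomal chromosomes per trio).  For
noncoding DNMs the coding expectation is scaled by the ratio of the gene's
noncoding length to its coding length, under the assumption that per-bp
mutability is the same in the noncoding footprint as in the CDS.  By default
the noncoding length is the count of noncoding footprint positions with
CADD >= 15 (the effective target after the CADD filter on observed DNMs); a
raw-bp mode pairs the unfiltered footprint length with unfiltered noncoding
counts for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import CODING_CLASSES, GENIC_NONCODING_CLASSES, INTERGENIC, MISSENSE
from .genemodel import GeneSet
from .stats import BONFERRONI_ALPHA, bh_fdr, bonferroni, poisson_case_only

log = logging.getLogger(__name__)

TEST_FAMILIES = ("coding", "missense", "lgd", "noncoding_genic",
                 "noncoding_intergenic")


@dataclass(frozen=True)
class CohortConfig:
    cohort_id: str
    n_case_trios: int
    n_control_trios: int

    def __post_init__(self) -> None:
        if self.n_case_trios <= 0 or self.n_control_trios <= 0:
            raise ValueError("trio counts must be positive")


def expected_coding(p_gene: float, n_trios: int) -> float:
    """Expected coding DNM count: rate x trios x 2 autosomal chromosomes."""
    if p_gene <= 0 or n_trios <= 0:
        raise ValueError("p_gene and n_trios must be positive")
    return p_gene * n_trios * 2.0


def expected_noncoding_point(
    p_gene: float, n_trios: int, noncoding_functional_length: float,
    coding_length: float,
) -> float:
    """Coding expectation scaled by the noncoding/coding length ratio."""
    if coding_length <= 0:
        raise ValueError("coding_length must be positive")
    if noncoding_functional_length < 0:
        raise ValueError("noncoding length must be non-negative")
    return expected_coding(p_gene, n_trios) * (
        noncoding_functional_length / coding_length
    )


def _observed_counts(dnms: pd.DataFrame, family: str,
                     cadd_threshold: float | None) -> pd.Series:
    """Qualifying case DNM count per gene for one test family."""
    df = dnms
    if "cohort" in df.columns:
        df = df[df["cohort"] == "case"]
    if "filter_status" in df.columns:
        df = df[df["filter_status"] == "pass"]
    if family == "coding":
        sel = df["region_class"].isin(CODING_CLASSES)
    elif family == "missense":
        sel = df["consequence"] == MISSENSE
    elif family == "lgd":
        sel = df["is_lgd"].astype(bool)
    elif family == "noncoding_genic":
        sel = df["region_class"].isin(GENIC_NONCODING_CLASSES)
    elif family == "noncoding_intergenic":
        sel = df["region_class"] == INTERGENIC
    else:
        raise ValueError(f"unknown test family {family!r}")
    if family.startswith("noncoding") and cadd_threshold is not None:
        sel &= df["cadd"].astype(float) >= cadd_threshold
    sub = df[sel & (df["gene_id"] != "") & df["gene_id"].notna()]
    return sub.groupby("gene_id").size()


def run_point_tests(
    dnms: pd.DataFrame,
    rates: pd.DataFrame,
    genes: GeneSet,
    cohort: CohortConfig,
    families: tuple[str, ...] = TEST_FAMILIES,
    nc_length_mode: str = "cadd15",
) -> pd.DataFrame:
    """Per-gene case-only Poisson tests for the requested families.

    Every gene in the rate table is reported (observed = 0 gives p = 1) so
    corrections run over a declared universe.  Genes carrying DNMs but absent
    from the rate table are reported with missing expectation and no p-value.
    """
    if nc_length_mode not in ("cadd15", "raw"):
        raise ValueError("nc_length_mode must be 'cadd15' or 'raw'")
    n = cohort.n_case_trios
    by_id = rates.set_index("gene_id")
    rows = []
    for family in families:
        cadd_thr = 15.0 if (family.startswith("noncoding")
                            and nc_length_mode == "cadd15") else None
        observed = _observed_counts(dnms, family, cadd_thr)
        universe = list(by_id.index)
        extra = sorted(set(observed.index) - set(universe))
        if extra:
            log.warning("point test %s: %d genes with DNMs lack rate entries",
                        family, len(extra))
        for gene_id in universe + extra:
            obs = int(observed.get(gene_id, 0))
            expected, p = np.nan, np.nan
            if gene_id in by_id.index:
                p_col = {"missense": "p_missense", "lgd": "p_lgd"}.get(
                    family, "p_total")
                p_gene = float(by_id.loc[gene_id, p_col])
                if family.startswith("noncoding"):
                    gene = genes[gene_id] if gene_id in genes.genes else None
                    if gene is None or gene.coding_length == 0:
                        log.warning("point test %s: %s has no coding length; "
                                    "skipped", family, gene_id)
                        rows.append((gene_id, family, obs, np.nan, np.nan))
                        continue
                    nc_len = (gene.noncoding_functional_length
                              if nc_length_mode == "cadd15"
                              else gene.noncoding_footprint_length)
                    if nc_len is None:
                        raise ValueError(
                            f"{gene_id}: noncoding functional length not set")
                    expected = expected_noncoding_point(
                        p_gene, n, nc_len, gene.coding_length)
                else:
                    expected = expected_coding(p_gene, n)
                p = poisson_case_only(obs, expected) if expected > 0 else (
                    1.0 if obs == 0 else poisson_case_only(obs, 0.0))
            rows.append((gene_id, family, obs, expected, p))
    out = pd.DataFrame(
        rows, columns=["gene_id", "test_family", "observed", "expected", "p_value"]
    )
    # corrections within each family over the declared universe
    out["p_bonferroni"] = np.nan
    out["q_fdr"] = np.nan
    out["significant_bonferroni"] = False
    for family in families:
        m = out["test_family"] == family
        valid = m & out["p_value"].notna()
        n_tests = int(valid.sum())
        if n_tests == 0:
            continue
        out.loc[valid, "p_bonferroni"] = bonferroni(
            out.loc[valid, "p_value"], m=n_tests)
        out.loc[valid, "q_fdr"] = bh_fdr(out.loc[valid, "p_value"], m=n_tests)
        out.loc[valid, "significant_bonferroni"] = (
            out.loc[valid, "p_value"] < BONFERRONI_ALPHA)
    return out
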