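"""Case-only segment-based enrichment test on 1 kb constraint bins.

Each 1 kb window carries an expected rare-variant count from a population
constraint map; beta is that count over the all-bin mean.  The cohort's
average noncoding DNM count per bin (over the analyzed bin universe) times
beta gives each bin's expected DNM count; a gene's expectation is the sum
over its assigned bins, compared to the observed count with the same Poisson
upper-tail kernel as the point test.

Because beta's global normalization (mean 1 over ALL bins) does not hold over
a restricted universe (e.g. genic-noncoding bins only), compute_background by
default renormalizes beta within the analyzed universe, which makes expected
counts conserve the observed total exactly under a single-assignment mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .annotate import GENIC_NONCODING_CLASSES, INTERGENIC
from .genemodel import GeneSet
from .simulate import BIN_WIDTH
from .stats import BONFERRONI_ALPHA, bh_fdr, bonferroni, poisson_case_only

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentBackground:
    average_count_1kb: float
    n_noncoding_bins: int
    #: multiplier restoring mean(beta) = 1 over the analyzed universe
    beta_scale: float = 1.0


def compute_beta(expected_rare: np.ndarray) -> np.ndarray:
    """beta = per-bin expected rare-variant count over the all-bin mean."""
    expected_rare = np.asarray(expected_rare, dtype=float)
    mean = expected_rare.mean()
    if mean <= 0:
        raise ValueError("mean expected rare-variant count must be positive")
    return expected_rare / mean


def _bin_key(bins: pd.DataFrame) -> pd.Index:
    return pd.Index(list(zip(bins["chrom"], bins["start"])), tupleize_cols=False)


def _dnm_bin_index(dnms: pd.DataFrame) -> pd.Index:
    starts = ((dnms["pos"].astype(int) - 1) // BIN_WIDTH) * BIN_WIDTH
    return pd.Index(list(zip(dnms["chrom"], starts)), tupleize_cols=False)


def _qualifying_dnms(dnms: pd.DataFrame, mode: str,
                     cadd_min: float | None) -> pd.DataFrame:
    df = dnms
    if "cohort" in df.columns:
        df = df[df["cohort"] == "case"]
    if "filter_status" in df.columns:
        df = df[df["filter_status"] == "pass"]
    if mode == "genic":
        df = df[df["region_class"].isin(GENIC_NONCODING_CLASSES)]
    elif mode == "intergenic":
        df = df[df["region_class"] == INTERGENIC]
    else:
        raise ValueError(f"unknown segment mode {mode!r}")
    if cadd_min is not None:
        df = df[df["cadd"].astype(float) >= cadd_min]
    return df


def universe_bins(bins: pd.DataFrame, mode: str) -> pd.DataFrame:
    flag = "genic_noncoding" if mode == "genic" else "intergenic"
    return bins[bins["region_flag"] == flag]


def compute_background(
    dnms: pd.DataFrame,
    bins: pd.DataFrame,
    mode: str = "genic",
    cadd_min: float | None = None,
    renormalize_beta: bool = True,
) -> SegmentBackground:
    """Average qualifying DNM count per bin over the mode's bin universe."""
    uni = universe_bins(bins, mode)
    if len(uni) == 0:
        raise ValueError(f"no {mode} bins in the bin table")
    df = _qualifying_dnms(dnms, mode, cadd_min)
    in_universe = _dnm_bin_index(df).isin(_bin_key(uni))
    count = int(in_universe.sum())
    scale = float(len(uni) / uni["beta"].sum()) if renormalize_beta else 1.0
    return SegmentBackground(
        average_count_1kb=count / len(uni),
        n_noncoding_bins=len(uni),
        beta_scale=scale,
    )


def expected_bin_count(background: SegmentBackground, beta: float) -> float:
    """Expected DNM count for one bin: average_count_1kb x beta."""
    return background.average_count_1kb * beta * background.beta_scale


def assign_bins_to_genes(
    bins: pd.DataFrame,
    genes: GeneSet,
    mode: str = "genic",
    single_assignment: bool = False,
) -> dict[str, list[int]]:
    """Map gene_id -> row indices of its bins.

    genic mode: a genic-noncoding bin maps to every gene whose noncoding
    footprint it overlaps by >=1 bp (or only the longest-overlap gene when
    ``single_assignment``); coding-overlap bins are excluded.  intergenic
    mode: each intergenic bin maps to the gene nearest its midpoint.
    """
    uni = universe_bins(bins, mode)
    mapping: dict[str, list[int]] = {}
    for idx, row in zip(uni.index, uni.itertuples(index=False)):
        s, e = int(row.start), int(row.start) + BIN_WIDTH
        chrom = row.chrom
        if mode == "genic":
            hits = []
            for g in genes.by_chrom.get(chrom, []):
                if g.footprint_end <= s or g.footprint_start >= e:
                    continue
                ov = iv.intersect_length([(s, e)], g.noncoding_footprint)
                if ov > 0:
                    hits.append((ov, g.gene_id))
            if not hits:
                continue
            if single_assignment:
                hits = [max(hits, key=lambda h: (h[0], h[1]))]
            for _, gid in hits:
                mapping.setdefault(gid, []).append(idx)
        else:
            mid = s + BIN_WIDTH // 2
            best = None
            for g in genes.by_chrom.get(chrom, []):
                if g.footprint_start <= mid < g.footprint_end:
                    dist = 0
                else:
                    dist = (g.footprint_start - mid if mid < g.footprint_start
                            else mid - g.footprint_end + 1)
                if best is None or (dist, g.gene_id) < best:
                    best = (dist, g.gene_id)
            if best is not None:
                mapping.setdefault(best[1], []).append(idx)
    return mapping


def run_segment_test(
    dnms: pd.DataFrame,
    bins: pd.DataFrame,
    genes: GeneSet,
    mode: str = "genic",
    background: SegmentBackground | None = None,
    single_assignment: bool = False,
    cadd_min: float | None = None,
) -> pd.DataFrame:
    """Per-gene segment test; genes without assigned bins are omitted."""
    if background is None:
        background = compute_background(dnms, bins, mode, cadd_min=cadd_min)
    mapping = assign_bins_to_genes(bins, genes, mode, single_assignment)
    missing = [g.gene_id for g in genes if g.gene_id not in mapping]
    if missing:
        log.info("segment test %s: %d genes with no assigned bins omitted",
                 mode, len(missing))
    df = _qualifying_dnms(dnms, mode, cadd_min)
    dnm_bins = _dnm_bin_index(df)
    counts = pd.Series(dnm_bins).value_counts()
    rows = []
    for gene_id, idxs in sorted(mapping.items()):
        sub = bins.loc[idxs]
        keys = list(zip(sub["chrom"], sub["start"]))
        observed = int(sum(counts.get(k, 0) for k in keys))
        expected = float(sum(expected_bin_count(background, b)
                             for b in sub["beta"]))
        p = poisson_case_only(observed, expected) if expected > 0 else (
            1.0 if observed == 0 else poisson_case_only(observed, 0.0))
        rows.append((gene_id, f"segment_{mode}", observed, expected,
                     len(idxs), p))
    out = pd.DataFrame(rows, columns=["gene_id", "test_family", "observed",
                                      "expected", "n_bins", "p_value"])
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p_value"], m=len(out))
        out["q_fdr"] = bh_fdr(out["p_value"], m=len(out))
        out["significant_bonferroni"] = out["p_value"] < BONFERRONI_ALPHA
    return out


def bin_diagnostics(bins: pd.DataFrame, dnms: pd.DataFrame,
                    background: SegmentBackground, mode: str = "genic",
                    cadd_min: float | None = None) -> pd.DataFrame:
    """Per-bin observed/expected table for the analyzed universe."""
    uni = universe_bins(bins, mode).copy()
    df = _qualifying_dnms(dnms, mode, cadd_min)
    counts = pd.Series(_dnm_bin_index(df)).value_counts()
    key = _bin_key(uni)
    uni["observed"] = [int(counts.get(k, 0)) for k in key]
    uni["expected"] = [expected_bin_count(background, b) for b in uni["beta"]]
    return uni
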