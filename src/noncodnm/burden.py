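"""Case-control burden tests over gene sets and cross-class evidence combination.

Burden compares carrier fractions (subjects with at least one qualifying DNM
in the tested unit) between case and control arms with a one-sided Fisher
exact test; fold change is the ratio of carrier fractions, and odds ratios
use a Haldane-Anscombe 0.5 correction when a cell is empty.  A
DNM-count-based mode is provided alongside the subject-based default.

Evidence combination is hierarchical Fisher: per cohort, coding and noncoding
point p-values combine into a per-cohort combined p; across cohorts, each
family's p-values combine into a cross-cohort family p; the overall
cross-cohort p combines the per-cohort combined p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import CODING_CLASSES, GENIC_NONCODING_CLASSES, INTERGENIC
from .segment_test import BIN_WIDTH, _dnm_bin_index
from .stats import (
    BurdenTable2x2,
    fisher_combined,
    fisher_exact_onesided,
    fold_change,
    odds_ratio_corrected,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BurdenResult:
    set_id: str
    table: BurdenTable2x2
    fold_change: float
    p_value: float
    odds_ratio: float
    unit: str


def _qualify(dnms: pd.DataFrame, classes: str, cadd_min: float | None,
             bins: pd.DataFrame | None, gnocchi_min: float | None) -> pd.DataFrame:
    df = dnms[dnms["filter_status"] == "pass"] if "filter_status" in dnms else dnms
    if classes == "coding":
        df = df[df["region_class"].isin(CODING_CLASSES)]
    elif classes == "noncoding":
        df = df[df["region_class"].isin(GENIC_NONCODING_CLASSES)]
    elif classes == "noncoding_all":
        df = df[df["region_class"].isin(GENIC_NONCODING_CLASSES)
                | (df["region_class"] == INTERGENIC)]
    elif classes != "all":
        raise ValueError(f"unknown class selector {classes!r}")
    if cadd_min is not None:
        df = df[df["cadd"].astype(float) >= cadd_min]
    if gnocchi_min is not None:
        if bins is None:
            raise ValueError("gnocchi_min requires the bin table")
        high = bins[bins["gnocchi"] > gnocchi_min]
        key = pd.Index(list(zip(high["chrom"], high["start"])), tupleize_cols=False)
        df = df[_dnm_bin_index(df).isin(key)]
    return df


def gene_set_burden(
    dnms: pd.DataFrame,
    gene_set: set[str],
    n_case: int,
    n_control: int,
    set_id: str = "set",
    classes: str = "coding",
    cadd_min: float | None = None,
    bins: pd.DataFrame | None = None,
    gnocchi_min: float | None = None,
    unit: str = "subjects",
) -> BurdenResult:
    """Carrier-based (or count-based) case-control burden over a gene set."""
    if not gene_set:
        raise ValueError("empty gene set")
    df = _qualify(dnms, classes, cadd_min, bins, gnocchi_min)
    df = df[df["gene_id"].isin(gene_set)]
    if unit == "subjects":
        x_case = df.loc[df["cohort"] == "case", "child_id"].nunique()
        x_ctrl = df.loc[df["cohort"] == "control", "child_id"].nunique()
        denom_case, denom_ctrl = n_case, n_control
    elif unit == "counts":
        x_case = int((df["cohort"] == "case").sum())
        x_ctrl = int((df["cohort"] == "control").sum())
        # count-based fold change normalizes per trio; Fisher table uses
        # DNM counts against the cohort totals of qualifying DNMs
        denom_case, denom_ctrl = n_case, n_control
    else:
        raise ValueError("unit must be 'subjects' or 'counts'")
    table = BurdenTable2x2(a=x_case, b=max(denom_case - x_case, 0),
                           c=x_ctrl, d=max(denom_ctrl - x_ctrl, 0))
    return BurdenResult(
        set_id=set_id,
        table=table,
        fold_change=fold_change(x_case, denom_case, x_ctrl, denom_ctrl),
        p_value=fisher_exact_onesided(table),
        odds_ratio=odds_ratio_corrected(table),
        unit=unit,
    )


def burden_results_table(results: list[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id, "case_carriers": r.table.a,
                "control_carriers": r.table.c, "n_case": r.table.n_case,
                "n_control": r.table.n_control, "fold_change": r.fold_change,
                "p_value": r.p_value, "odds_ratio": r.odds_ratio, "unit": r.unit,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Fisher combination across families and cohorts


def combine_point_results(
    point_by_cohort: dict[str, pd.DataFrame],
    coding_family: str = "coding",
    noncoding_family: str = "noncoding_genic",
) -> pd.DataFrame:
    """Table-4-style combined evidence per gene.

    Emits per-cohort coding/noncoding/combined p-values, cross-cohort
    per-family combined p-values, and the overall p (Fisher over the
    per-cohort combined p-values).
    """
    per_cohort: dict[str, pd.DataFrame] = {}
    for cohort_id, df in point_by_cohort.items():
        cod = df[df["test_family"] == coding_family].set_index("gene_id")
        non = df[df["test_family"] == noncoding_family].set_index("gene_id")
        gene_ids = cod.index.union(non.index)
        rows = {}
        for gid in gene_ids:
            p_c = float(cod["p_value"].get(gid, np.nan))
            p_n = float(non["p_value"].get(gid, np.nan))
            ps = [p for p in (p_c, p_n) if np.isfinite(p)]
            rows[gid] = {
                f"obs_coding_{cohort_id}": int(cod["observed"].get(gid, 0)),
                f"exp_coding_{cohort_id}": float(cod["expected"].get(gid, np.nan)),
                f"obs_noncoding_{cohort_id}": int(non["observed"].get(gid, 0)),
                f"exp_noncoding_{cohort_id}": float(non["expected"].get(gid, np.nan)),
                f"p_coding_{cohort_id}": p_c,
                f"p_noncoding_{cohort_id}": p_n,
                f"p_combined_{cohort_id}": fisher_combined(ps) if ps else np.nan,
            }
        per_cohort[cohort_id] = pd.DataFrame.from_dict(rows, orient="index")
    out = pd.concat(per_cohort.values(), axis=1)
    cohorts = list(point_by_cohort)
    if len(cohorts) > 1:
        for family, col in (("coding", "p_coding"), ("noncoding", "p_noncoding")):
            cols = [f"{col}_{c}" for c in cohorts]
            out[f"p_{family}_cross"] = [
                fisher_combined([p for p in row if np.isfinite(p)])
                if any(np.isfinite(p) for p in row) else np.nan
                for row in out[cols].to_numpy()
            ]
        comb_cols = [f"p_combined_{c}" for c in cohorts]
        out["p_overall"] = [
            fisher_combined([p for p in row if np.isfinite(p)])
            if any(np.isfinite(p) for p in row) else np.nan
            for row in out[comb_cols].to_numpy()
        ]
    else:
        out["p_overall"] = out[f"p_combined_{cohorts[0]}"]
    out.index.name = "gene_id"
    return out.reset_index().sort_values("p_overall").reset_index(drop=True)
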