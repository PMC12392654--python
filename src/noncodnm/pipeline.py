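"""Configuration-driven end-to-end orchestration.

simulate -> call -> annotate -> point/segment tests -> burden -> combine ->
summary, with a JSON run manifest recording config, file digests, row counts
and per-stage wall-clock.  Each stage failure aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    CODING_CLASSES,
    GENIC_NONCODING_CLASSES,
    INTERGENIC,
    annotate_calls,
)
from .burden import burden_results_table, combine_point_results, gene_set_burden
from .caller import (
    DnmCall,
    FilterThresholds,
    apply_blacklist,
    apply_dnm_filters,
    calls_to_table,
    collapse_nearby,
    detect_candidate_dnms,
    normalize_and_split,
    read_family_vcf,
)
from .genemodel import write_gene_table
from .point_test import CohortConfig, run_point_tests
from .segment_test import run_segment_test
from .simulate import (
    SimulationConfig,
    TrioCohort,
    attach_noncoding_functional_lengths,
    generate_gene_models,
    generate_gnocchi_bins,
    generate_mask,
    generate_mutation_rate_table,
    generate_reference,
    generate_site_scores,
    plant_start_and_stop_codons,
    simulate_trio_cohort,
    write_mask_bed,
)

log = logging.getLogger(__name__)

TABLE_SCHEMA_VERSION = "1"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_cohort(config: SimulationConfig) -> TrioCohort:
    """Generate every synthetic track and the trio cohort in one call."""
    reference = generate_reference(config)
    genes = generate_gene_models(config, reference)
    plant_start_and_stop_codons(reference, genes)
    rates = generate_mutation_rate_table(genes, config)
    scores = generate_site_scores(config, reference)
    attach_noncoding_functional_lengths(genes, scores)
    mask = generate_mask(config, reference)
    return simulate_trio_cohort(config, reference, genes, rates, scores, mask)


def call_family(records: list[dict], child_id: str, cohort_label: str,
                reference_seqs: dict[str, str] | None,
                thresholds: FilterThresholds,
                mask=None, af_table=None) -> tuple[list[DnmCall], list[DnmCall]]:
    normalized = normalize_and_split(records, reference_seqs)
    candidates, excluded = detect_candidate_dnms(normalized, child_id, cohort_label)
    apply_dnm_filters(candidates, thresholds, mask, af_table)
    return candidates, excluded


def call_cohort(cohort: TrioCohort,
                thresholds: FilterThresholds | None = None) -> list[DnmCall]:
    """In-memory calling: normalize, detect, filter, annotate, collapse.

    Calls dropped by the 100 bp same-gene collapse are marked 'collapsed';
    candidate-stage exclusions are not returned.
    """
    th = thresholds or FilterThresholds()
    seqs = cohort.reference.sequences()
    all_calls: list[DnmCall] = []
    for fam in cohort.families:
        candidates, _ = call_family(fam.records, fam.child_id, fam.cohort,
                                    seqs, th, cohort.mask, cohort.af_table)
        all_calls.extend(candidates)
    annotate_calls(all_calls, cohort.genes, seqs, cohort.scores,
                   cohort.reference.chrom_lengths)
    apply_blacklist(all_calls, th)
    passed = [c for c in all_calls if c.passed]
    kept = set(id(c) for c in collapse_nearby(passed, th.collapse_window_bp))
    for c in passed:
        if id(c) not in kept:
            c.filter_status = "collapsed"
    return all_calls


def summarize_cohort(dnms: pd.DataFrame, n_case: int, n_control: int) -> pd.DataFrame:
    """Per-arm DNM counts by class with per-trio means (Table-2 style)."""
    rows = []
    for arm, n in (("case", n_case), ("control", n_control)):
        df = dnms[(dnms["cohort"] == arm)]
        if "filter_status" in df.columns:
            df = df[df["filter_status"] == "pass"]
        coding = df["region_class"].isin(CODING_CLASSES)
        genic_nc = df["region_class"].isin(GENIC_NONCODING_CLASSES)
        interg = df["region_class"] == INTERGENIC
        cadd15 = df["cadd"].astype(float) >= 15.0
        noncoding = genic_nc | interg
        rows.append(
            {
                "cohort": arm,
                "n_trios": n,
                "coding_dnms": int(coding.sum()),
                "lgd_dnms": int(df["is_lgd"].astype(bool).sum()),
                "missense_dnms": int((df["consequence"] == "missense").sum()),
                "noncoding_dnms": int(noncoding.sum()),
                "noncoding_cadd15": int((noncoding & cadd15).sum()),
                "genic_noncoding_dnms": int(genic_nc.sum()),
                "genic_noncoding_cadd15": int((genic_nc & cadd15).sum()),
                "intergenic_dnms": int(interg.sum()),
                "intergenic_cadd15": int((interg & cadd15).sum()),
                "coding_dnms_per_trio": round(float(coding.sum()) / n, 2),
                "noncoding_dnms_per_trio": round(float(noncoding.sum()) / n, 2),
            }
        )
    return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the full pipeline from a YAML-style config dict; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "schema_version": TABLE_SCHEMA_VERSION,
        "config": config,
        "stages": {},
        "outputs": {},
    }
    thresholds = FilterThresholds.from_dict(config.get("thresholds", {}))

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3)
                }
                return False

        return _Ctx()

    sim_cfg_dict = dict(config.get("simulate", {}))
    if seed is not None:
        sim_cfg_dict["seed"] = seed
    if "bin_gamma" in sim_cfg_dict:
        sim_cfg_dict["bin_gamma"] = tuple(sim_cfg_dict["bin_gamma"])
    with stage("simulate"):
        sim_cfg = SimulationConfig(**sim_cfg_dict)
        cohort = build_cohort(sim_cfg)
        cohort.reference.write_fasta(out / "reference.fa")
        write_gene_table(cohort.genes, out / "genes.tsv")
        cohort.rates.to_csv(out / "rates.tsv", sep="\t", index=False)
        bins = generate_gnocchi_bins(sim_cfg, cohort.reference, cohort.genes)
        bins.to_csv(out / "bins.tsv", sep="\t", index=False)
        write_mask_bed(cohort.mask, out / "mask.bed")
        cohort.write_af_table(out / "af.tsv")
        cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        if config.get("write_vcfs", False):
            cohort.write_vcfs(out / "vcf")

    with stage("call-dnm"):
        calls = call_cohort(cohort, thresholds)
        dnms = calls_to_table(calls)
        dnms.to_csv(out / "dnms.tsv", sep="\t", index=False)

    with stage("annotate"):
        annotated = dnms  # annotation is fused into calling for in-memory runs
        annotated.to_csv(out / "annotated.tsv", sep="\t", index=False)

    cohort_cfg = CohortConfig(
        cohort_id=config.get("cohort_id", "sim"),
        n_case_trios=sim_cfg.n_case_trios,
        n_control_trios=sim_cfg.n_control_trios,
    )
    with stage("test-point"):
        point = run_point_tests(
            annotated, cohort.rates, cohort.genes, cohort_cfg,
            families=tuple(config.get(
                "point_families",
                ("coding", "missense", "lgd", "noncoding_genic",
                 "noncoding_intergenic"))),
            nc_length_mode=config.get("nc_length_mode", "cadd15"),
        )
        point.to_csv(out / "point.tsv", sep="\t", index=False)

    with stage("test-segment"):
        seg_frames = []
        for mode in config.get("segment_modes", ("genic",)):
            seg_frames.append(run_segment_test(annotated, bins, cohort.genes,
                                               mode=mode))
        segment = pd.concat(seg_frames) if seg_frames else pd.DataFrame()
        segment.to_csv(out / "segment.tsv", sep="\t", index=False)

    with stage("burden"):
        results = []
        sets = dict(config.get("gene_sets", {}))
        if not sets:
            sets = {"all_genes": [g.gene_id for g in cohort.genes]}
        for set_id, ids in sets.items():
            for classes, cadd_min in (("coding", None), ("noncoding", 15.0)):
                results.append(
                    gene_set_burden(
                        annotated, set(ids), cohort_cfg.n_case_trios,
                        cohort_cfg.n_control_trios,
                        set_id=f"{set_id}:{classes}",
                        classes=classes, cadd_min=cadd_min,
                    )
                )
        burden_df = burden_results_table(results)
        burden_df.to_csv(out / "burden.tsv", sep="\t", index=False)

    with stage("combine"):
        combined = combine_point_results({cohort_cfg.cohort_id: point})
        combined.to_csv(out / "combined.tsv", sep="\t", index=False)

    with stage("report"):
        summary = summarize_cohort(annotated, cohort_cfg.n_case_trios,
                                   cohort_cfg.n_control_trios)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        for p in sorted(out.glob("*.tsv")) + [out / "reference.fa", out / "mask.bed"]:
            if p.exists():
                manifest["outputs"][p.name] = {
                    "sha256": _digest(p),
                    "rows": sum(1 for _ in open(p)) - 1 if p.suffix == ".tsv" else None,
                }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
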