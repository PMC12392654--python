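"""Trio de novo mutation (DNM) detection and filtering.

A candidate DNM is a normalized biallelic variant at which the child is
heterozygous for the alternate allele and both parents are homozygous
reference.  Candidates are then screened with eight hard filters (child
alt-allele depth, child/parent genotype quality, parent depth, population
allele frequency, low-mappability mask, child allele balance, problem-gene
blacklist) plus a within-gene 100 bp collapse that keeps only the most severe
call per cluster.  Every violated criterion is recorded, not just the first,
so per-filter exclusion counts can be reported.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

MISSING_GT = "./."

# filter reason codes
R_AD_ALT = "ad_alt"
R_CHILD_GQ = "child_gq"
R_PARENT_GQ = "parent_gq"
R_PARENT_DP = "parent_dp"
R_POP_AF = "pop_af"
R_MAPPABILITY = "mappability"
R_AB = "ab"
R_AB_UNDEF = "ab_undefined"
R_BLACKLIST = "blacklist"
# candidate-stage exclusion reasons
R_PARENT_MISSING = "parent_missing"
R_CHILD_HOM_ALT = "child_hom_alt"
R_PARENT_CARRIER = "parent_carrier"
R_NOT_CARRIER = "child_not_carrier"

FILTER_REASONS = (
    R_AD_ALT, R_CHILD_GQ, R_PARENT_GQ, R_PARENT_DP,
    R_POP_AF, R_MAPPABILITY, R_AB, R_AB_UNDEF, R_BLACKLIST,
)


@dataclass(frozen=True)
class TrioVariantRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    child_gt: str
    mother_gt: str
    father_gt: str
    child_ad_ref: int
    child_ad_alt: int
    child_dp: int
    mother_dp: int
    father_dp: int
    child_gq: int
    mother_gq: int
    father_gq: int
    pop_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based and >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class FilterThresholds:
    """Hard filters applied to candidate DNMs (see module docstring)."""

    min_child_ad_alt: int = 6
    min_child_gq: int = 25
    min_parent_gq: int = 20
    min_parent_dp_exclusive: int = 8  # strict: parent DP must be > this
    max_pop_af: float = 0.001
    ab_low: float = 0.25
    ab_high: float = 0.75
    collapse_window_bp: int = 100
    blacklist_gene_prefixes: tuple[str, ...] = ("HLA", "MUC")

    def __post_init__(self) -> None:
        if not (0 <= self.ab_low < self.ab_high <= 1):
            raise ValueError("require 0 <= ab_low < ab_high <= 1")
        if min(self.min_child_ad_alt, self.min_child_gq, self.min_parent_gq,
               self.min_parent_dp_exclusive, self.collapse_window_bp) < 0 \
                or self.max_pop_af < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterThresholds":
        d = dict(d)
        if "blacklist_gene_prefixes" in d:
            d["blacklist_gene_prefixes"] = tuple(d["blacklist_gene_prefixes"])
        return cls(**d)


@dataclass
class DnmCall:
    record: TrioVariantRecord
    child_id: str
    cohort: str  # "case" | "control"
    filter_status: str = "pass"
    fail_reasons: set[str] = field(default_factory=set)
    gene_id: str | None = None
    region_class: str | None = None
    consequence: str | None = None
    is_lgd: bool = False
    severity_rank: int | None = None
    cadd: float | None = None
    fathmm: float | None = None
    spliceai: float | None = None

    @property
    def passed(self) -> bool:
        return self.filter_status == "pass"


# ---------------------------------------------------------------------------
# normalization


def left_align(pos: int, ref: str, alt: str, chrom_seq: str) -> tuple[int, str, str]:
    """Normalize one biallelic allele pair against the chromosome sequence.

    Trims the shared right context (extending left through the reference when
    an allele would become empty), then the shared left context, yielding the
    parsimonious left-most representation. ``pos`` is 1-based.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if ref[-1] == alt[-1] and (len(ref) == 1 or len(alt) == 1) and pos > 1:
            base = chrom_seq[pos - 2].upper()
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_and_split(
    raw_records: list[dict],
    reference: dict[str, str] | None = None,
) -> list[TrioVariantRecord]:
    """Split multi-allelic sites and left-align indels.

    ``raw_records`` are dicts with chrom/pos/ref/alts plus per-sample fields
    where AD is the full per-allele list (ref first).  Spanning-deletion ('*')
    and symbolic alts are dropped with a logged count.  Input order is stable.
    """
    out: list[TrioVariantRecord] = []
    dropped = 0
    for rec in raw_records:
        ref = rec["ref"]
        for ai, alt in enumerate(rec["alts"]):
            if alt == "*" or alt.startswith("<"):
                dropped += 1
                continue
            pos = rec["pos"]
            if reference is not None and rec["chrom"] in reference:
                pos, nref, nalt = left_align(pos, ref, alt, reference[rec["chrom"]])
            else:
                nref, nalt = ref, alt
            ads = rec.get("child_ad", [])
            out.append(
                TrioVariantRecord(
                    chrom=rec["chrom"], pos=pos, ref=nref, alt=nalt,
                    child_gt=_split_gt(rec["child_gt"], ai + 1),
                    mother_gt=_split_gt(rec["mother_gt"], ai + 1),
                    father_gt=_split_gt(rec["father_gt"], ai + 1),
                    child_ad_ref=int(ads[0]) if ads else 0,
                    child_ad_alt=int(ads[ai + 1]) if len(ads) > ai + 1 else 0,
                    child_dp=int(rec.get("child_dp", 0)),
                    mother_dp=int(rec.get("mother_dp", 0)),
                    father_dp=int(rec.get("father_dp", 0)),
                    child_gq=int(rec.get("child_gq", 0)),
                    mother_gq=int(rec.get("mother_gq", 0)),
                    father_gq=int(rec.get("father_gq", 0)),
                    pop_af=rec.get("pop_af"),
                )
            )
    if dropped:
        log.info("normalize_and_split: dropped %d symbolic/star alt alleles", dropped)
    return out


def _split_gt(gt: str, allele_index: int) -> str:
    """Re-express a genotype against one alt allele (others become ref)."""
    if gt in (MISSING_GT, ".", "."):
        return MISSING_GT
    sep = "|" if "|" in gt else "/"
    parts = []
    for a in gt.replace("|", "/").split("/"):
        if a == ".":
            return MISSING_GT
        parts.append("1" if int(a) == allele_index else "0")
    return sep.join(sorted(parts))


# ---------------------------------------------------------------------------
# candidate detection and filtering


def _is_homref(gt: str) -> bool:
    return gt.replace("|", "/") in ("0/0",)


def _alt_dose(gt: str) -> int:
    return gt.replace("|", "/").count("1")


def detect_candidate_dnms(
    records: list[TrioVariantRecord],
    child_id: str,
    cohort: str,
) -> tuple[list[DnmCall], list[DnmCall]]:
    """Return (candidates, excluded) DnmCalls for one trio.

    A candidate requires a heterozygous child and both parents homozygous
    reference; anything else is excluded with a stage-specific reason.
    """
    candidates: list[DnmCall] = []
    excluded: list[DnmCall] = []
    for r in records:
        call = DnmCall(record=r, child_id=child_id, cohort=cohort)
        if MISSING_GT in (r.mother_gt, r.father_gt):
            call.filter_status = "excluded"
            call.fail_reasons = {R_PARENT_MISSING}
            excluded.append(call)
            continue
        dose = _alt_dose(r.child_gt) if r.child_gt != MISSING_GT else 0
        if dose == 0:
            call.filter_status = "excluded"
            call.fail_reasons = {R_NOT_CARRIER}
            excluded.append(call)
        elif dose == 2:
            call.filter_status = "excluded"
            call.fail_reasons = {R_CHILD_HOM_ALT}
            excluded.append(call)
        elif not (_is_homref(r.mother_gt) and _is_homref(r.father_gt)):
            call.filter_status = "excluded"
            call.fail_reasons = {R_PARENT_CARRIER}
            excluded.append(call)
        else:
            candidates.append(call)
    return candidates, excluded


def allele_balance(child_ad_ref: int, child_ad_alt: int) -> float:
    """Fraction of the child's reads supporting the alternate allele."""
    total = child_ad_ref + child_ad_alt
    if total <= 0:
        raise ValueError("allele balance undefined at zero depth")
    return child_ad_alt / total


class MappabilityMask:
    """0-based half-open BED intervals of low-mappability regions."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        from . import intervals as iv

        self._ivs = {c: iv.merge(v) for c, v in (intervals or {}).items() if v}
        for c, ivs in self._ivs.items():
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"malformed mask interval {c}:{s}-{e}")

    @classmethod
    def from_bed(cls, path: str | Path) -> "MappabilityMask":
        ivs: dict[str, list[tuple[int, int]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, *_ = line.split("\t")
            s, e = int(start), int(end)
            if e <= s:
                raise ValueError(f"malformed mask interval {chrom}:{s}-{e}")
            ivs.setdefault(chrom, []).append((s, e))
        return cls(ivs)

    def contains(self, chrom: str, pos1: int) -> bool:
        """Test a 1-based variant position against the mask."""
        ivs = self._ivs.get(chrom)
        if not ivs:
            return False
        p = pos1 - 1
        i = bisect_right(ivs, (p, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= p < ivs[i][1]


def load_af_table(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): float(r.af)
        for r in df.itertuples(index=False)
    }


def apply_dnm_filters(
    candidates: list[DnmCall],
    thresholds: FilterThresholds | None = None,
    mask: MappabilityMask | None = None,
    af_table: dict[tuple[str, int, str, str], float] | None = None,
) -> list[DnmCall]:
    """Label every candidate pass/fail, accumulating all violated criteria.

    A missing population allele frequency is treated as 0 (a novel variant
    passes the frequency filter).  Blacklist matching needs gene annotation
    and is applied here only when ``gene_id`` is already attached; the
    pipeline re-checks it after annotation.
    """
    th = thresholds or FilterThresholds()
    for call in candidates:
        r = call.record
        reasons: set[str] = set()
        if r.child_ad_alt < th.min_child_ad_alt:
            reasons.add(R_AD_ALT)
        if r.child_gq < th.min_child_gq:
            reasons.add(R_CHILD_GQ)
        if r.mother_gq < th.min_parent_gq or r.father_gq < th.min_parent_gq:
            reasons.add(R_PARENT_GQ)
        if (r.mother_dp <= th.min_parent_dp_exclusive
                or r.father_dp <= th.min_parent_dp_exclusive):
            reasons.add(R_PARENT_DP)
        af = r.pop_af
        if af is None and af_table is not None:
            af = af_table.get((r.chrom, r.pos, r.ref, r.alt))
        if af is not None and af >= th.max_pop_af:
            reasons.add(R_POP_AF)
        if mask is not None and mask.contains(r.chrom, r.pos):
            reasons.add(R_MAPPABILITY)
        if r.child_ad_ref + r.child_ad_alt <= 0:
            reasons.add(R_AB_UNDEF)
        else:
            ab = allele_balance(r.child_ad_ref, r.child_ad_alt)
            if not (th.ab_low <= ab <= th.ab_high):
                reasons.add(R_AB)
        if call.gene_id and call.region_class != "intergenic" and any(
            call.gene_id.startswith(p) for p in th.blacklist_gene_prefixes
        ):
            reasons.add(R_BLACKLIST)
        call.fail_reasons = reasons
        call.filter_status = "fail" if reasons else "pass"
    return candidates


def apply_blacklist(calls: list[DnmCall], thresholds: FilterThresholds | None = None) -> None:
    """Re-check the gene blacklist on annotated calls (post-annotation step).

    Applies to variants located inside a blacklisted gene's footprint, not to
    intergenic variants merely assigned to one as their nearest gene.
    """
    th = thresholds or FilterThresholds()
    for call in calls:
        if call.gene_id and call.region_class != "intergenic" and any(
            call.gene_id.startswith(p) for p in th.blacklist_gene_prefixes
        ):
            call.fail_reasons.add(R_BLACKLIST)
            call.filter_status = "fail"


def collapse_nearby(calls: list[DnmCall], window: int = 100) -> list[DnmCall]:
    """Within each (child, gene), keep one call per <=window-bp cluster.

    Clusters are transitive (single linkage on position); the survivor is the
    call with the highest severity rank, ties broken by smaller position.
    Calls without gene annotation pass through unclustered.
    """
    annotated = [c for c in calls if c.gene_id is not None]
    unannotated = [c for c in calls if c.gene_id is None]
    if unannotated:
        log.info("collapse_nearby: %d calls without gene annotation passed through",
                 len(unannotated))
    kept: list[DnmCall] = []
    groups: dict[tuple[str, str], list[DnmCall]] = {}
    for c in annotated:
        groups.setdefault((c.child_id, c.gene_id), []).append(c)
    for group in groups.values():
        group.sort(key=lambda c: c.record.pos)
        cluster: list[DnmCall] = []
        for c in group:
            if cluster and c.record.pos - cluster[-1].record.pos > window:
                kept.append(_most_severe(cluster))
                cluster = []
            cluster.append(c)
        if cluster:
            kept.append(_most_severe(cluster))
    kept.extend(unannotated)
    kept.sort(key=lambda c: (c.child_id, c.record.chrom, c.record.pos, c.record.alt))
    return kept


def _most_severe(cluster: list[DnmCall]) -> DnmCall:
    return min(
        cluster,
        key=lambda c: (-(c.severity_rank if c.severity_rank is not None else -1),
                       c.record.pos),
    )


# ---------------------------------------------------------------------------
# VCF I/O


def read_family_vcf(path: str | Path) -> tuple[str, list[dict]]:
    """Read a single-family VCF (samples child, mother, father in order).

    Returns (child_sample_name, raw records) suitable for normalize_and_split.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if len(samples) != 3:
        raise ValueError(f"{path}: expected 3 samples (child, mother, father), "
                         f"got {samples}")
    records = []
    for v in vcf:
        gts = [_fmt_gt(v.genotypes[i]) for i in range(3)]
        ad = v.format("AD")
        dp = v.format("DP")
        gq = v.format("GQ")
        records.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alts": list(v.ALT),
                "child_gt": gts[0],
                "mother_gt": gts[1],
                "father_gt": gts[2],
                "child_ad": [int(x) for x in ad[0]] if ad is not None else [],
                "child_dp": int(dp[0][0]) if dp is not None else 0,
                "mother_dp": int(dp[1][0]) if dp is not None else 0,
                "father_dp": int(dp[2][0]) if dp is not None else 0,
                "child_gq": int(gq[0][0]) if gq is not None else 0,
                "mother_gq": int(gq[1][0]) if gq is not None else 0,
                "father_gq": int(gq[2][0]) if gq is not None else 0,
            }
        )
    vcf.close()
    return samples[0], records


def _fmt_gt(gt: list) -> str:
    alleles = gt[:-1]
    if any(a is None or a < 0 for a in alleles):
        return MISSING_GT
    sep = "|" if gt[-1] else "/"
    return sep.join(str(a) for a in alleles)


def calls_to_table(calls: list[DnmCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        r = c.record
        rows.append(
            {
                "child_id": c.child_id, "cohort": c.cohort,
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "child_gt": r.child_gt, "mother_gt": r.mother_gt,
                "father_gt": r.father_gt,
                "child_ad_ref": r.child_ad_ref, "child_ad_alt": r.child_ad_alt,
                "child_dp": r.child_dp, "mother_dp": r.mother_dp,
                "father_dp": r.father_dp, "child_gq": r.child_gq,
                "mother_gq": r.mother_gq, "father_gq": r.father_gq,
                "pop_af": r.pop_af,
                "filter_status": c.filter_status,
                "fail_reasons": ";".join(sorted(c.fail_reasons)),
                "gene_id": c.gene_id or "",
                "region_class": c.region_class or "",
                "consequence": c.consequence or "",
                "is_lgd": c.is_lgd,
                "cadd": c.cadd, "fathmm": c.fathmm, "spliceai": c.spliceai,
            }
        )
    return pd.DataFrame(rows)
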