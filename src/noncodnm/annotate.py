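"""Region classification, coding consequences, and functional-score annotation.

Every variant receives exactly one region class, chosen by the precedence
exonic > splicing > ncRNA_exonic/ncRNA_splicing > UTR5/UTR3 > intronic >
ncRNA_intronic > upstream/downstream > intergenic across all genes whose
footprint (transcript span +/- 1 kb) contains it.  "Splicing" means within
2 bp of an exon/intron boundary on the intron side; for coding genes such
calls are treated as likely-gene-disrupting (LGD), for noncoding genes they
stay noncoding (ncRNA_splicing).  Coding consequences are derived by codon
translation with strand handling; indels whose length is not a multiple of
three are frameshifts.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from . import intervals as iv
from .caller import DnmCall
from .genemodel import GeneModel, GeneSet

log = logging.getLogger(__name__)

# region classes, in classification precedence order
EXONIC = "exonic"
SPLICING = "splicing"
NCRNA_EXONIC = "ncRNA_exonic"
NCRNA_SPLICING = "ncRNA_splicing"
UTR5 = "UTR5"
UTR3 = "UTR3"
INTRONIC = "intronic"
NCRNA_INTRONIC = "ncRNA_intronic"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
INTERGENIC = "intergenic"

REGION_PRECEDENCE = (
    EXONIC, SPLICING, NCRNA_EXONIC, NCRNA_SPLICING, UTR5, UTR3,
    INTRONIC, NCRNA_INTRONIC, UPSTREAM, DOWNSTREAM, INTERGENIC,
)
_PREC = {c: i for i, c in enumerate(REGION_PRECEDENCE)}

#: region classes counted as "coding DNMs" in the enrichment tests
CODING_CLASSES = frozenset({EXONIC, SPLICING})
#: genic noncoding classes (the point-based noncoding test universe)
GENIC_NONCODING_CLASSES = frozenset(
    {NCRNA_EXONIC, NCRNA_SPLICING, UTR5, UTR3, INTRONIC, NCRNA_INTRONIC,
     UPSTREAM, DOWNSTREAM}
)

# consequence classes
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
STOPGAIN = "stopgain"
STOPLOSS = "stoploss"
STARTLOSS = "startloss"
FS_INS = "frameshift_insertion"
FS_DEL = "frameshift_deletion"
NONFS_INDEL = "nonframeshift_indel"
SPLICE_CSQ = "splicing"
OTHER = "other"

LGD_CLASSES = frozenset({FS_INS, FS_DEL, STARTLOSS, STOPGAIN, STOPLOSS, SPLICE_CSQ})

# severity used by the 100 bp collapse rule (higher = kept)
SEVERITY = {
    **{c: 9 for c in LGD_CLASSES},
    MISSENSE: 8,
    SYNONYMOUS: 7,
    NONFS_INDEL: 7,
    OTHER: 7,
}
REGION_SEVERITY = {
    NCRNA_SPLICING: 6, UTR5: 5, UTR3: 5, INTRONIC: 4,
    UPSTREAM: 3, DOWNSTREAM: 3, NCRNA_EXONIC: 2, NCRNA_INTRONIC: 2,
    INTERGENIC: 1,
}

CADD_THRESHOLD = 15.0       # inclusive (>=)
FATHMM_THRESHOLD = 0.5      # exclusive (>)
SPLICEAI_THRESHOLD = 0.8    # inclusive (>=)


# ---------------------------------------------------------------------------
# per-gene piecewise class map


@lru_cache(maxsize=None)
def _class_map(gene: GeneModel) -> tuple[tuple[int, ...], tuple[str, ...]]:
    """Disjoint (bounds, classes) partition of the gene footprint."""
    pieces: list[tuple[int, int, str]] = []
    fs, fe = gene.footprint_start, gene.footprint_end
    up_left = UPSTREAM if gene.strand == "+" else DOWNSTREAM
    dn_right = DOWNSTREAM if gene.strand == "+" else UPSTREAM
    if fs < gene.tx_start:
        pieces.append((fs, gene.tx_start, up_left))
    if gene.tx_end < fe:
        pieces.append((gene.tx_end, fe, dn_right))
    if gene.is_coding:
        for s, e in gene.cds:
            pieces.append((s, e, EXONIC))
        for s, e in gene.splice_regions:
            pieces.append((s, e, SPLICING))
        for s, e in iv.subtract(gene.exons, gene.cds):
            left = e <= gene.cds_start
            if gene.strand == "+":
                cls = UTR5 if left else UTR3
            else:
                cls = UTR3 if left else UTR5
            pieces.append((s, e, cls))
        intron_cls = INTRONIC
    else:
        for s, e in gene.exons:
            pieces.append((s, e, NCRNA_EXONIC))
        for s, e in gene.splice_regions:
            pieces.append((s, e, NCRNA_SPLICING))
        intron_cls = NCRNA_INTRONIC
    covered = [(s, e) for s, e, _ in pieces]
    for s, e in iv.subtract([(gene.tx_start, gene.tx_end)], covered):
        pieces.append((s, e, intron_cls))
    pieces.sort()
    bounds = tuple(s for s, _, _ in pieces)
    classes = tuple(c for _, _, c in pieces)
    return bounds, classes


def _classify_in_gene(gene: GeneModel, pos0: int) -> str:
    bounds, classes = _class_map(gene)
    i = bisect_right(bounds, pos0) - 1
    return classes[i]


def classify_region(
    chrom: str, pos: int, genes: GeneSet, chrom_lengths: dict[str, int] | None = None,
) -> tuple[str | None, str]:
    """Assign (gene_id or None, region class) to a 1-based variant position."""
    if pos < 1 or (
        chrom_lengths is not None and pos > chrom_lengths.get(chrom, float("inf"))
    ):
        raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
    p = pos - 1
    best: tuple[int, str, str] | None = None
    for g in genes.overlapping(chrom, p):
        cls = _classify_in_gene(g, p)
        key = (_PREC[cls], g.gene_id)
        if best is None or key < (best[0], best[2]):
            best = (_PREC[cls], cls, g.gene_id)
    if best is None:
        return None, INTERGENIC
    return best[2], best[1]


def assign_nearest_gene(chrom: str, pos: int, genes: GeneSet) -> str | None:
    """Nearest gene (footprint-boundary distance) for an intergenic variant."""
    p = pos - 1
    candidates = genes.by_chrom.get(chrom, [])
    if not candidates:
        log.warning("assign_nearest_gene: no genes on %s", chrom)
        return None
    best: tuple[int, str] | None = None
    for g in candidates:
        if g.footprint_start <= p < g.footprint_end:
            raise ValueError(
                f"{chrom}:{pos} lies inside the footprint of {g.gene_id}; "
                "nearest-gene assignment applies to intergenic variants only"
            )
        dist = g.footprint_start - p if p < g.footprint_start else p - g.footprint_end + 1
        if best is None or (dist, g.gene_id) < best:
            best = (dist, g.gene_id)
    return best[1]


# ---------------------------------------------------------------------------
# coding consequences


def _cds_sequence(gene: GeneModel, chrom_seq: str) -> str:
    s = "".join(chrom_seq[a:b] for a, b in gene.cds)
    return s if gene.strand == "+" else str(Seq(s).reverse_complement())


def _cds_offset(gene: GeneModel, pos0: int) -> int | None:
    """Offset of a genomic position within the strand-oriented CDS."""
    off = 0
    hit = None
    for a, b in gene.cds:
        if a <= pos0 < b:
            hit = off + (pos0 - a)
        off += b - a
    if hit is None:
        return None
    return hit if gene.strand == "+" else off - 1 - hit


def coding_consequence(
    pos: int, ref: str, alt: str, gene: GeneModel, chrom_seq: str,
    region_class: str,
) -> tuple[str, bool]:
    """Return (consequence class, is_LGD) for an exonic/splicing variant."""
    if region_class == SPLICING:
        return SPLICE_CSQ, True
    if region_class != EXONIC:
        raise ValueError("coding_consequence requires an exonic or splicing call")
    if len(ref) != len(alt):
        diff = abs(len(ref) - len(alt))
        if diff % 3 != 0:
            return (FS_INS, True) if len(alt) > len(ref) else (FS_DEL, True)
        return NONFS_INDEL, False
    if len(ref) != 1:
        return OTHER, False  # MNVs not decomposed further
    cds_len = gene.coding_length
    if cds_len % 3 != 0:
        log.warning("%s: CDS length %d not divisible by 3", gene.gene_id, cds_len)
        return OTHER, False
    p = pos - 1
    off = _cds_offset(gene, p)
    if off is None:
        return OTHER, False
    cds_seq = _cds_sequence(gene, chrom_seq)
    if gene.strand == "+":
        base_ref, base_alt = ref.upper(), alt.upper()
    else:
        base_ref = str(Seq(ref).reverse_complement())
        base_alt = str(Seq(alt).reverse_complement())
    if cds_seq[off].upper() != base_ref:
        log.warning("%s: reference mismatch at CDS offset %d", gene.gene_id, off)
    codon_i = off // 3
    within = off % 3
    ref_codon = cds_seq[codon_i * 3: codon_i * 3 + 3].upper()
    alt_codon = ref_codon[:within] + base_alt + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return STARTLOSS, True
    if ref_aa != "*" and alt_aa == "*":
        return STOPGAIN, True
    if ref_aa == "*" and alt_aa != "*":
        return STOPLOSS, True
    if ref_aa == alt_aa:
        return SYNONYMOUS, False
    return MISSENSE, False


def severity_rank(region_class: str, consequence: str | None) -> int:
    if consequence is not None and consequence in SEVERITY:
        return SEVERITY[consequence]
    if consequence == SPLICE_CSQ:
        return SEVERITY[SPLICE_CSQ]
    return REGION_SEVERITY.get(region_class, 0)


# ---------------------------------------------------------------------------
# scores


def attach_scores(calls: list[DnmCall], scores) -> list[DnmCall]:
    """Attach CADD/FATHMM-like/SpliceAI-like scores (never imputed).

    ``scores`` provides ``at(chrom, pos1) -> (cadd, fathmm, spliceai)`` with
    None for missing values.
    """
    for c in calls:
        cadd, fathmm, spliceai = scores.at(c.record.chrom, c.record.pos)
        c.cadd, c.fathmm, c.spliceai = cadd, fathmm, spliceai
    return calls


def score_flags(call: DnmCall) -> dict[str, bool]:
    return {
        "cadd15": call.cadd is not None and call.cadd >= CADD_THRESHOLD,
        "fathmm_patho": call.fathmm is not None and call.fathmm > FATHMM_THRESHOLD,
        "spliceai_high": call.spliceai is not None and call.spliceai >= SPLICEAI_THRESHOLD,
    }


def compute_noncoding_functional_length(gene: GeneModel, scores) -> int:
    """Count noncoding footprint positions with CADD >= 15.

    ``scores`` provides ``cadd_range(chrom, start0, end0) -> ndarray`` covering
    the requested half-open window; a gap raises naming the region.
    """
    total = 0
    for s, e in gene.noncoding_footprint:
        arr = scores.cadd_range(gene.chrom, s, e)
        if arr is None or len(arr) != e - s or np.any(np.isnan(arr)):
            raise ValueError(
                f"score track does not cover {gene.chrom}:{s}-{e} "
                f"(gene {gene.gene_id})"
            )
        total += int(np.count_nonzero(arr >= CADD_THRESHOLD))
    return total


def annotate_calls(
    calls: list[DnmCall],
    genes: GeneSet,
    reference: dict[str, str] | None = None,
    scores=None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[DnmCall]:
    """Full annotation pass: region class, nearest gene, consequence, scores."""
    for c in calls:
        gene_id, cls = classify_region(c.record.chrom, c.record.pos, genes, chrom_lengths)
        c.region_class = cls
        if cls == INTERGENIC:
            c.gene_id = assign_nearest_gene(c.record.chrom, c.record.pos, genes)
        else:
            c.gene_id = gene_id
        if cls in CODING_CLASSES and reference is not None:
            gene = genes[gene_id]
            c.consequence, c.is_lgd = coding_consequence(
                c.record.pos, c.record.ref, c.record.alt, gene,
                reference[c.record.chrom], cls,
            )
        c.severity_rank = severity_rank(
            cls if cls != INTERGENIC else INTERGENIC, c.consequence
        )
    if scores is not None:
        attach_scores(calls, scores)
    return calls
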