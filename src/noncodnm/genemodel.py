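"""Gene models: transcript/exon/CDS intervals and derived mutational targets.

A gene is stored refFlat-style (transcript span, exon list, single CDS span);
CDS intervals are the intersection of exons with the CDS span.  The genic
"footprint" is the transcript span extended by a flank (default 1 kb) on both
sides, which is the target region for both region classification and the
noncoding arm of the point-based enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import pandas as pd

from . import intervals as iv

DEFAULT_FLANK = 1000
#: intronic bases on each side of an exon boundary treated as canonical splicing
SPLICE_WINDOW = 2


@dataclass(eq=False)  # identity-hashed: instances are cached by the annotator
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int  # 0-based half-open
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: int  # cds_start == cds_end means noncoding (ncRNA) gene
    cds_end: int
    flank: int = DEFAULT_FLANK
    pli: float | None = None
    noncoding_functional_length: int | None = None

    def __post_init__(self) -> None:
        self.exons = iv.merge(self.exons)
        if not (self.tx_start <= self.exons[0][0] and self.exons[-1][1] <= self.tx_end):
            raise ValueError(f"{self.gene_id}: exons outside transcript bounds")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    # ---- derived interval tracks -------------------------------------------------
    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @cached_property
    def cds(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return []
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    @property
    def footprint_start(self) -> int:
        return max(0, self.tx_start - self.flank)

    @property
    def footprint_end(self) -> int:
        return self.tx_end + self.flank

    @property
    def coding_length(self) -> int:
        return iv.total_length(self.cds)

    @cached_property
    def splice_regions(self) -> list[tuple[int, int]]:
        """Intronic SPLICE_WINDOW-bp windows flanking internal exon boundaries."""
        out = []
        for i, (s, e) in enumerate(self.exons):
            if i > 0:
                out.append((s - SPLICE_WINDOW, s))
            if i < len(self.exons) - 1:
                out.append((e, e + SPLICE_WINDOW))
        return iv.merge(out) if out else []

    @cached_property
    def coding_span(self) -> list[tuple[int, int]]:
        """CDS plus canonical splice dinucleotides (counted as coding targets)."""
        if not self.is_coding:
            return []
        return iv.merge(self.cds + self.splice_regions)

    @cached_property
    def noncoding_footprint(self) -> list[tuple[int, int]]:
        """Footprint minus the coding span; the noncoding mutational target."""
        return iv.subtract([(self.footprint_start, self.footprint_end)], self.coding_span)

    @property
    def footprint_length(self) -> int:
        return self.footprint_end - self.footprint_start

    @property
    def noncoding_footprint_length(self) -> int:
        return iv.total_length(self.noncoding_footprint)


class GeneSet:
    """An indexed, non-overlapping-per-chromosome collection of gene models."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene ids")
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.footprint_start)):
            self.by_chrom.setdefault(g.chrom, []).append(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        """Genes whose footprint contains 0-based position ``pos``."""
        return [
            g
            for g in self.by_chrom.get(chrom, [])
            if g.footprint_start <= pos < g.footprint_end
        ]


_COLUMNS = [
    "gene_id", "chrom", "strand", "tx_start", "tx_end",
    "exon_starts", "exon_ends", "cds_start", "cds_end", "pli",
    "noncoding_functional_length",
]


def write_gene_table(genes: GeneSet | list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
                "cds_start": g.cds_start,
                "cds_end": g.cds_end,
                "pli": "" if g.pli is None else g.pli,
                "noncoding_functional_length": (
                    "" if g.noncoding_functional_length is None
                    else g.noncoding_functional_length
                ),
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path, flank: int = DEFAULT_FLANK) -> GeneSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        nfl = getattr(row, "noncoding_functional_length", None)
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                exons=list(zip(starts, ends)),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                flank=flank,
                pli=None if pd.isna(row.pli) else float(row.pli),
                noncoding_functional_length=None if pd.isna(nfl) else int(nfl),
            )
        )
    return GeneSet(genes)


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    if not out:
        raise ValueError(f"empty gene list: {path}")
    return out
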