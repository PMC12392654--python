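"""Synthetic trio cohort generator.

Produces a fully self-contained scaled-down study: a random reference genome,
non-overlapping gene models with realistic length-correlated mutation rates, a
deterministic per-position functional-score track (~1.8% of sites at CADD>=15,
matching the tail the CADD 15 threshold selects), 1 kb constraint bins with
heterogeneous expected rare-variant counts, and per-family trio VCFs with
planted de novo mutations (DNMs) plus engineered low-quality decoys and
inherited background variants.

The scaled-down genome stands in for the whole genome: the per-child coding
DNM mean (default 1.27) and the genome-wide per-child DNM mean (default 90)
are spread across the simulated genes, so downstream per-trio summary
statistics match the real-cohort scale even though the sequence is small.
Within a gene, DNMs fall uniformly over the footprint at the gene's coding
per-base-pair rate, which is exactly the assumption the noncoding point test
makes (noncoding mutability per bp equals coding mutability per bp).

One integer seed drives a named stream per stage, so outputs are
byte-identical under a fixed config and adding stages never perturbs earlier
draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _rng
from . import intervals as iv
from .caller import FILTER_REASONS, MappabilityMask
from .genemodel import GeneModel, GeneSet

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BIN_WIDTH = 1000


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 40
    n_case_trios: int = 50
    n_control_trios: int = 50
    #: per-child mean DNM count over the whole (scaled-down) genome;
    #: None = density-matched to the genic per-bp rate
    genomewide_dnm_rate: float | None = 90.0
    #: per-child mean coding DNM count, spread over the simulated genes
    coding_dnms_per_child: float = 1.27
    enrichment_spec: dict[str, float] = field(default_factory=dict)
    depth_mean: float = 30.0
    depth_dispersion: float = 10.0
    decoys_per_child: float = 0.0
    background_hets_per_child: int = 3
    indel_fraction: float = 0.08
    ncrna_fraction: float = 0.1
    n_blacklist_genes: int = 0
    mask_fraction: float = 0.003
    # gene architecture
    flank: int = 1000
    mean_exons: float = 4.0
    mean_cds_length: int = 1200
    cds_length_sigma: float = 0.6
    mean_intron_length: int = 2000
    utr_length: int = 200
    intergenic_gap: int = 6000
    rate_factor_sigma: float = 0.25
    #: gamma (shape, scale) for 1 kb bin expected rare-variant counts
    bin_gamma: tuple[float, float] = (4.0, 0.25)

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes",
                     "n_case_trios", "n_control_trios"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be at least 10 kb")
        if any(f < 0 for f in self.enrichment_spec.values()):
            raise ValueError("enrichment fold multipliers must be >= 0")


class Reference:
    """In-memory random reference; sequences as uint8 codes with str views."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays
        self._str_cache: dict[str, str] = {}

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.arrays.items()}

    def sequence(self, chrom: str) -> str:
        if chrom not in self._str_cache:
            self._str_cache[chrom] = BASES[self.arrays[chrom]].tobytes().decode()
        return self._str_cache[chrom]

    def sequences(self) -> dict[str, str]:
        return {c: self.sequence(c) for c in self.arrays}

    def base(self, chrom: str, pos0: int) -> str:
        return chr(BASES[self.arrays[chrom][pos0]])

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.arrays:
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def generate_reference(config: SimulationConfig) -> Reference:
    """n_chromosomes random A/C/G/T sequences, deterministic under the seed."""
    rng = _rng.stream(config.seed, "reference")
    arrays = {}
    for i in range(config.n_chromosomes):
        arrays[f"chr{i + 1}"] = rng.integers(
            0, 4, size=config.chrom_length, dtype=np.uint8
        )
    return Reference(arrays)


# ---------------------------------------------------------------------------
# gene models


def generate_gene_models(config: SimulationConfig, reference: Reference) -> GeneSet:
    """Pack non-overlapping gene models (footprints included) onto chromosomes."""
    rng = _rng.stream(config.seed, "genes")
    chroms = list(reference.arrays)
    cursors = {c: config.flank + 100 for c in chroms}
    genes: list[GeneModel] = []
    n_black = min(config.n_blacklist_genes, config.n_genes)
    for gi in range(config.n_genes):
        if gi < n_black:
            prefix = "HLA" if gi % 2 == 0 else "MUC"
            gene_id = f"{prefix}S{gi:03d}"
        else:
            gene_id = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        is_ncrna = rng.random() < config.ncrna_fraction
        n_exons = 2 + rng.poisson(max(config.mean_exons - 2, 0.0))
        introns = np.maximum(
            rng.lognormal(np.log(config.mean_intron_length), 0.5, n_exons - 1), 60
        ).astype(int)
        if is_ncrna:
            exon_lens = np.maximum(
                rng.lognormal(np.log(300), 0.5, n_exons), 50
            ).astype(int)
            utr5 = utr3 = 0
            cds_len = 0
        else:
            cds_len = int(
                np.maximum(
                    rng.lognormal(np.log(config.mean_cds_length),
                                  config.cds_length_sigma), 90)
            )
            cds_len -= cds_len % 3
            parts = rng.multinomial(cds_len - 9 * n_exons, np.ones(n_exons) / n_exons)
            exon_lens = parts + 9
            utr5 = max(int(rng.lognormal(np.log(config.utr_length), 0.4)), 20)
            utr3 = max(int(rng.lognormal(np.log(config.utr_length), 0.4)), 20)
        gap = int(rng.lognormal(np.log(config.intergenic_gap), 0.3))
        gap = max(gap, 2 * config.flank + 200)
        # try chromosomes in round-robin order starting from the least full
        placed = False
        for chrom in sorted(chroms, key=lambda c: cursors[c]):
            start = cursors[chrom] + gap
            tx_len = utr5 + int(exon_lens.sum()) + int(introns.sum()) + utr3
            end = start + tx_len
            if end + config.flank + 100 <= reference.chrom_lengths[chrom]:
                genes.append(
                    _build_gene(gene_id, chrom, strand, start, exon_lens, introns,
                                utr5, utr3, cds_len, config.flank, rng)
                )
                cursors[chrom] = end
                placed = True
                break
        if not placed:
            raise ValueError(
                f"infeasible packing: could not place gene {gi + 1} of "
                f"{config.n_genes} on a {config.n_chromosomes}x"
                f"{config.chrom_length} bp genome"
            )
    return GeneSet(genes)


def _build_gene(gene_id, chrom, strand, start, exon_lens, introns, utr5, utr3,
                cds_len, flank, rng) -> GeneModel:
    exons = []
    cur = start
    first_exon_extra = utr5 if strand == "+" else utr3
    last_exon_extra = utr3 if strand == "+" else utr5
    for i, el in enumerate(exon_lens):
        length = int(el)
        if i == 0:
            length += first_exon_extra
        if i == len(exon_lens) - 1:
            length += last_exon_extra
        exons.append((cur, cur + length))
        cur += length
        if i < len(exon_lens) - 1:
            cur += int(introns[i])
    tx_start, tx_end = start, cur
    if cds_len > 0:
        cds_start = start + first_exon_extra
        cds_end = exons[-1][1] - last_exon_extra
    else:
        cds_start = cds_end = tx_start
    g = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                  tx_start=tx_start, tx_end=tx_end, exons=exons,
                  cds_start=cds_start, cds_end=cds_end, flank=flank,
                  pli=float(np.round(rng.beta(0.3, 0.3), 4)))
    if cds_len > 0:
        assert g.coding_length == cds_len and cds_len % 3 == 0
    return g


def plant_start_and_stop_codons(reference: Reference, genes: GeneSet) -> None:
    """Overwrite the first/last CDS codons with ATG / TAA (strand-aware).

    Keeps simulated coding sequences translatable with a proper start and
    stop, so consequence calls on planted variants behave like real genes.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    code = {b: i for i, b in enumerate("ACGT")}
    for g in genes:
        if not g.is_coding:
            continue
        arr = reference.arrays[g.chrom]
        cds_pos = [p for s, e in g.cds for p in range(s, e)]
        first, last = cds_pos[:3], cds_pos[-3:]
        if g.strand == "+":
            for p, b in zip(first, "ATG"):
                arr[p] = code[b]
            for p, b in zip(last, "TAA"):
                arr[p] = code[b]
        else:
            for p, b in zip(last, "ATG"[::-1]):
                arr[p] = code[comp[b]]
            for p, b in zip(first, "TAA"[::-1]):
                arr[p] = code[comp[b]]
    reference._str_cache.clear()


# ---------------------------------------------------------------------------
# mutation-rate table


def rate_length(gene: GeneModel) -> int:
    """Length that drives a gene's mutation rate (CDS, or exons for ncRNA)."""
    return gene.coding_length if gene.is_coding else iv.total_length(gene.exons)


def generate_mutation_rate_table(genes: GeneSet, config: SimulationConfig) -> pd.DataFrame:
    """Per-gene DNM probabilities, proportional to coding length times a
    log-normal gene factor, scaled so that the cohort-wide per-child coding
    DNM mean equals ``coding_dnms_per_child``."""
    rng = _rng.stream(config.seed, "rates")
    ids, lengths = zip(*[(g.gene_id, rate_length(g)) for g in genes])
    factors = rng.lognormal(0.0, config.rate_factor_sigma, len(ids))
    raw = np.asarray(lengths, dtype=float) * factors
    p_total = raw * (config.coding_dnms_per_child / 2.0) / raw.sum()
    mis_frac = rng.uniform(0.55, 0.68, len(ids))
    lgd_frac = rng.uniform(0.08, 0.16, len(ids))
    df = pd.DataFrame(
        {
            "gene_id": ids,
            "p_total": p_total,
            "p_missense": p_total * mis_frac,
            "p_lgd": p_total * lgd_frac,
            "rate_length": lengths,
        }
    )
    return df


# ---------------------------------------------------------------------------
# functional scores


class HashedScoreTrack:
    """Deterministic per-position functional scores from a counter-based hash.

    CADD-like scores are uniform on [0, 15) for 98.2% of positions and
    uniform on [15, 45) for the remaining 1.8%, so the >=15 tail matches the
    top ~1.8% the threshold is meant to select.  FATHMM-like scores are
    uniform on [0, 1]; SpliceAI-like delta scores are skewed toward 0.
    """

    CADD_TAIL = 0.018

    def __init__(self, seed: int, chrom_lengths: dict[str, int]):
        self.seed = seed
        self.chrom_lengths = dict(chrom_lengths)
        self._index = {c: i for i, c in enumerate(self.chrom_lengths)}

    def _u(self, name: str, chrom: str, pos0) -> np.ndarray:
        return _rng.position_u01(self.seed, name, self._index[chrom], pos0)

    def cadd(self, chrom: str, pos0) -> np.ndarray:
        u = self._u("cadd", chrom, pos0)
        lo = 15.0 * u / (1 - self.CADD_TAIL)
        hi = 15.0 + 30.0 * (u - (1 - self.CADD_TAIL)) / self.CADD_TAIL
        return np.where(u < 1 - self.CADD_TAIL, lo, hi)

    def fathmm(self, chrom: str, pos0) -> np.ndarray:
        return self._u("fathmm", chrom, pos0)

    def spliceai(self, chrom: str, pos0) -> np.ndarray:
        return self._u("spliceai", chrom, pos0) ** 8

    def cadd_range(self, chrom: str, start0: int, end0: int) -> np.ndarray:
        return self.cadd(chrom, np.arange(start0, end0, dtype=np.int64))

    def at(self, chrom: str, pos1: int):
        p = np.int64(pos1 - 1)
        return (
            float(self.cadd(chrom, p)),
            float(self.fathmm(chrom, p)),
            float(self.spliceai(chrom, p)),
        )

    def write_table(self, path: str | Path,
                    regions: dict[str, list[tuple[int, int]]] | None = None) -> None:
        """Write a (chrom, pos, cadd, fathmm, spliceai) TSV; 1-based positions."""
        frames = []
        regions = regions or {c: [(0, n)] for c, n in self.chrom_lengths.items()}
        for chrom, ivs in regions.items():
            for s, e in ivs:
                pos0 = np.arange(s, e, dtype=np.int64)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos0 + 1,
                            "cadd": np.round(self.cadd(chrom, pos0), 3),
                            "fathmm": np.round(self.fathmm(chrom, pos0), 4),
                            "spliceai": np.round(self.spliceai(chrom, pos0), 4),
                        }
                    )
                )
        pd.concat(frames).to_csv(path, sep="\t", index=False)


class TableScores:
    """Score lookup backed by a (chrom, pos, cadd[, fathmm, spliceai]) TSV."""

    def __init__(self, df: pd.DataFrame):
        self._by_chrom: dict[str, pd.DataFrame] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            self._by_chrom[str(chrom)] = sub.set_index("pos")

    @classmethod
    def from_file(cls, path: str | Path) -> "TableScores":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def at(self, chrom: str, pos1: int):
        sub = self._by_chrom.get(chrom)
        if sub is None or pos1 not in sub.index:
            return None, None, None
        row = sub.loc[pos1]
        get = lambda col: (None if col not in sub.columns or pd.isna(row[col])
                           else float(row[col]))
        return get("cadd"), get("fathmm"), get("spliceai")

    def cadd_range(self, chrom: str, start0: int, end0: int) -> np.ndarray:
        sub = self._by_chrom.get(chrom)
        if sub is None:
            raise ValueError(f"score table has no rows for {chrom}")
        window = sub["cadd"].reindex(np.arange(start0 + 1, end0 + 1))
        return window.to_numpy(dtype=float)


def generate_site_scores(config: SimulationConfig, reference: Reference) -> HashedScoreTrack:
    return HashedScoreTrack(config.seed, reference.chrom_lengths)


def attach_noncoding_functional_lengths(genes: GeneSet, scores) -> None:
    from .annotate import compute_noncoding_functional_length

    for g in genes:
        g.noncoding_functional_length = compute_noncoding_functional_length(g, scores)


# ---------------------------------------------------------------------------
# 1 kb constraint bins


def generate_gnocchi_bins(config: SimulationConfig, reference: Reference,
                          genes: GeneSet) -> pd.DataFrame:
    """Tile 1 kb windows with gamma-distributed expected rare-variant counts.

    beta is each bin's expected count over the all-bin mean (mean beta = 1).
    Bins are flagged coding_overlap (>=1 bp CDS), genic_noncoding (overlap a
    gene footprint, no CDS), or intergenic.
    """
    rng = _rng.stream(config.seed, "bins")
    rows = []
    for chrom, length in reference.chrom_lengths.items():
        n_bins = length // BIN_WIDTH
        if n_bins == 0:
            raise ValueError(f"{chrom}: shorter than one {BIN_WIDTH} bp bin")
        if length % BIN_WIDTH:
            log.info("%s: trailing %d bp not covered by bins", chrom,
                     length % BIN_WIDTH)
        cds = iv.merge([ivl for g in genes.by_chrom.get(chrom, [])
                        for ivl in g.cds]) if genes.by_chrom.get(chrom) else []
        fps = iv.merge([(g.footprint_start, g.footprint_end)
                        for g in genes.by_chrom.get(chrom, [])]) \
            if genes.by_chrom.get(chrom) else []
        for b in range(n_bins):
            s, e = b * BIN_WIDTH, (b + 1) * BIN_WIDTH
            if cds and iv.intersect_length([(s, e)], cds) > 0:
                flag = "coding_overlap"
            elif fps and iv.intersect_length([(s, e)], fps) > 0:
                flag = "genic_noncoding"
            else:
                flag = "intergenic"
            rows.append((chrom, s, flag))
    shape, scale = config.bin_gamma
    expected = rng.gamma(shape, scale, len(rows))
    gnocchi = rng.normal(0.0, 1.5, len(rows))
    df = pd.DataFrame(rows, columns=["chrom", "start", "region_flag"])
    df["expected_rare"] = expected
    df["gnocchi"] = gnocchi
    df["beta"] = expected / expected.mean()
    return df


# ---------------------------------------------------------------------------
# mappability mask


def generate_mask(config: SimulationConfig, reference: Reference) -> MappabilityMask:
    rng = _rng.stream(config.seed, "mask")
    ivs: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in reference.chrom_lengths.items():
        target = config.mask_fraction * length
        covered = 0
        out = []
        while covered < target:
            width = int(rng.integers(200, 2000))
            start = int(rng.integers(0, max(length - width, 1)))
            out.append((start, start + width))
            covered += width
        if out:
            ivs[chrom] = iv.merge(out)
    return MappabilityMask(ivs)


def write_mask_bed(mask: MappabilityMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in mask._ivs.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# trio cohort

DECOY_TYPES = ("ad_alt", "child_gq", "parent_gq", "parent_dp", "pop_af",
               "mappability", "ab", "blacklist")


@dataclass
class Family:
    child_id: str
    cohort: str  # "case" | "control"
    records: list[dict]


@dataclass
class TrioCohort:
    config: SimulationConfig
    reference: Reference
    genes: GeneSet
    rates: pd.DataFrame
    scores: HashedScoreTrack
    mask: MappabilityMask
    families: list[Family]
    truth: pd.DataFrame
    af_table: dict[tuple[str, int, str, str], float]

    def write_vcfs(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for fam in self.families:
            p = out_dir / f"{fam.child_id}.vcf"
            write_family_vcf(fam, p, self.reference.chrom_lengths)
            paths.append(p)
        return paths

    def write_af_table(self, path: str | Path) -> None:
        rows = [
            {"chrom": c, "pos": p, "ref": r, "alt": a, "af": af}
            for (c, p, r, a), af in sorted(self.af_table.items())
        ]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
            path, sep="\t", index=False
        )


def _genic_lambdas(genes: GeneSet, rates: pd.DataFrame,
                   enrichment: dict[str, float], blacklist_zero: bool):
    """Per-gene per-child expected DNM counts over the footprint."""
    lam = {}
    by_id = rates.set_index("gene_id")
    for g in genes:
        p = float(by_id.loc[g.gene_id, "p_total"])
        rl = int(by_id.loc[g.gene_id, "rate_length"])
        fold = enrichment.get(g.gene_id, 1.0)
        weight = 0.0 if (blacklist_zero and g.gene_id[:3] in ("HLA", "MUC")) \
            else 2.0 * p * (g.footprint_length / rl) * fold
        lam[g.gene_id] = weight
    return lam


def simulate_trio_cohort(
    config: SimulationConfig,
    reference: Reference,
    genes: GeneSet,
    rates: pd.DataFrame,
    scores: HashedScoreTrack | None = None,
    mask: MappabilityMask | None = None,
) -> TrioCohort:
    """Simulate case and control trios with planted DNMs and decoys.

    Per child the DNM count is Poisson with the configured genome-wide mean;
    each DNM falls in gene g with probability proportional to the gene's
    footprint-scaled rate (times the enrichment fold for case children) and
    in intergenic space otherwise.
    """
    unknown = set(config.enrichment_spec) - {g.gene_id for g in genes}
    if unknown:
        raise ValueError(f"enrichment_spec names unknown gene ids: {sorted(unknown)}")
    if scores is None:
        scores = generate_site_scores(config, reference)
    if mask is None:
        mask = generate_mask(config, reference)
    rng = _rng.stream(config.seed, "cohort")

    gene_list = list(genes)
    lam_case = _genic_lambdas(genes, rates, config.enrichment_spec, True)
    lam_ctrl = _genic_lambdas(genes, rates, {}, True)
    intergenic = {
        chrom: iv.subtract(
            [(0, length)],
            [(g.footprint_start, g.footprint_end)
             for g in genes.by_chrom.get(chrom, [])],
        )
        for chrom, length in reference.chrom_lengths.items()
    }
    ig_weights = np.array(
        [sum(e - s for s, e in ivs) for ivs in intergenic.values()], dtype=float
    )

    def total_rate(lam: dict[str, float]) -> tuple[float, float]:
        genic = sum(lam.values())
        if config.genomewide_dnm_rate is None:
            density = genic / max(sum(g.footprint_length for g in gene_list), 1)
            return genic + density * ig_weights.sum(), density * ig_weights.sum()
        if config.genomewide_dnm_rate < genic:
            raise ValueError(
                f"genomewide_dnm_rate {config.genomewide_dnm_rate} below the "
                f"genic DNM rate {genic:.3f} implied by the rate table"
            )
        return config.genomewide_dnm_rate, config.genomewide_dnm_rate - genic

    families: list[Family] = []
    truth_rows: list[dict] = []
    af_table: dict[tuple[str, int, str, str], float] = {}

    cohort_plan = [("case", i, lam_case) for i in range(config.n_case_trios)]
    cohort_plan += [("control", i, lam_ctrl) for i in range(config.n_control_trios)]
    # sites are unique cohort-wide (no recurrent sites), so a planted DNM can
    # never coincide with another family's background variant in the AF table
    used: set[tuple[str, int]] = set()
    for cohort, idx, lam in cohort_plan:
        child_id = f"{'case' if cohort == 'case' else 'ctrl'}{idx + 1:04d}"
        rate, ig_rate = total_rate(lam)
        n_dnm = rng.poisson(rate)
        probs = np.array([lam[g.gene_id] for g in gene_list] + [ig_rate]) / rate
        counts = rng.multinomial(n_dnm, probs)
        records: list[dict] = []
        for g, k in zip(gene_list, counts[:-1]):
            for _ in range(int(k)):
                site = _place_in_gene(rng, g, mask, used)
                if site is None:
                    continue
                records.append(_clean_dnm_record(rng, config, reference, site))
                truth_rows.append(_truth_row(child_id, cohort, records[-1],
                                             g.gene_id, "genic", "clean", ""))
        for _ in range(int(counts[-1])):
            site = _place_intergenic(rng, intergenic, ig_weights, mask, used)
            if site is None:
                continue
            records.append(_clean_dnm_record(rng, config, reference, site))
            truth_rows.append(_truth_row(child_id, cohort, records[-1],
                                         None, "intergenic", "clean", ""))
        # decoys
        n_decoy = rng.poisson(config.decoys_per_child)
        types = [t for t in DECOY_TYPES
                 if t != "blacklist" or config.n_blacklist_genes > 0]
        for _ in range(n_decoy):
            dtype = types[int(rng.integers(0, len(types)))]
            rec, gene_id, region = _decoy_record(
                rng, config, reference, genes, gene_list, intergenic, ig_weights,
                mask, used, dtype, af_table,
            )
            if rec is None:
                continue
            records.append(rec)
            truth_rows.append(_truth_row(child_id, cohort, rec, gene_id,
                                         region, "decoy", dtype))
        # inherited background heterozygotes
        for _ in range(config.background_hets_per_child):
            site = _place_intergenic(rng, intergenic, ig_weights, mask, used)
            if site is None:
                continue
            rec = _clean_dnm_record(rng, config, reference, site)
            carrier = "mother_gt" if rng.random() < 0.5 else "father_gt"
            rec[carrier] = "0/1"
            af = float(np.round(rng.uniform(0.01, 0.3), 4))
            af_table[(rec["chrom"], rec["pos"], rec["ref"], rec["alts"][0])] = af
            records.append(rec)
            truth_rows.append(_truth_row(child_id, cohort, rec, None,
                                         "intergenic", "background", ""))
        records.sort(key=lambda r: (r["chrom"], r["pos"], r["alts"][0]))
        families.append(Family(child_id=child_id, cohort=cohort, records=records))

    truth = pd.DataFrame(
        truth_rows,
        columns=["child_id", "cohort", "chrom", "pos", "ref", "alt",
                 "gene_id", "region", "kind", "decoy_target"],
    )
    return TrioCohort(config=config, reference=reference, genes=genes,
                      rates=rates, scores=scores, mask=mask, families=families,
                      truth=truth, af_table=af_table)


def _place_in_gene(rng, gene: GeneModel, mask: MappabilityMask,
                   used: set, tries: int = 50):
    for _ in range(tries):
        pos0 = int(rng.integers(gene.footprint_start, gene.footprint_end))
        if mask.contains(gene.chrom, pos0 + 1) or (gene.chrom, pos0) in used:
            continue
        used.add((gene.chrom, pos0))
        return gene.chrom, pos0
    return None


def _place_intergenic(rng, intergenic, ig_weights, mask: MappabilityMask,
                      used: set, tries: int = 50):
    chroms = list(intergenic)
    if ig_weights.sum() <= 0:
        return None
    probs = ig_weights / ig_weights.sum()
    for _ in range(tries):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        ivs = intergenic[chrom]
        widths = np.array([e - s for s, e in ivs], dtype=float)
        j = int(rng.choice(len(ivs), p=widths / widths.sum()))
        pos0 = int(rng.integers(ivs[j][0], ivs[j][1]))
        if mask.contains(chrom, pos0 + 1) or (chrom, pos0) in used:
            continue
        used.add((chrom, pos0))
        return chrom, pos0
    return None


def _alleles(rng, config: SimulationConfig, reference: Reference,
             chrom: str, pos0: int) -> tuple[int, str, str]:
    """Left-aligned (pos1, ref, alt); SNV or a short indel."""
    from .caller import left_align

    seq = reference.sequence(chrom)
    ref_base = seq[pos0]
    if rng.random() >= config.indel_fraction or pos0 + 4 >= len(seq):
        others = [b for b in "ACGT" if b != ref_base]
        return pos0 + 1, ref_base, others[int(rng.integers(0, 3))]
    if rng.random() < 0.5:  # insertion
        ins = "".join("ACGT"[int(rng.integers(0, 4))]
                      for _ in range(int(rng.integers(1, 4))))
        pos1, ref, alt = pos0 + 1, ref_base, ref_base + ins
    else:  # deletion
        dlen = int(rng.integers(1, 4))
        pos1, ref, alt = pos0 + 1, seq[pos0: pos0 + 1 + dlen], ref_base
    pos1, ref, alt = left_align(pos1, ref, alt, seq)
    return pos1, ref, alt


def _clean_metrics(rng, config: SimulationConfig) -> dict:
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)
    dp = max(int(rng.negative_binomial(nb_n, nb_p)), 20)
    lo, hi = int(np.ceil(0.3 * dp)), int(np.floor(0.7 * dp))
    alt = int(np.clip(rng.binomial(dp, 0.5), max(lo, 6), hi))
    pdp = lambda: max(int(rng.negative_binomial(nb_n, nb_p)), 12)
    return {
        "child_dp": dp, "child_ad": None, "child_alt": alt,
        "child_gq": int(rng.integers(40, 100)),
        "mother_dp": pdp(), "father_dp": pdp(),
        "mother_gq": int(rng.integers(40, 95)),
        "father_gq": int(rng.integers(40, 95)),
    }


def _record_from(chrom, pos1, ref, alt, m) -> dict:
    return {
        "chrom": chrom, "pos": pos1, "ref": ref, "alts": [alt],
        "child_gt": "0/1", "mother_gt": "0/0", "father_gt": "0/0",
        "child_ad": [m["child_dp"] - m["child_alt"], m["child_alt"]],
        "child_dp": m["child_dp"], "mother_dp": m["mother_dp"],
        "father_dp": m["father_dp"], "child_gq": m["child_gq"],
        "mother_gq": m["mother_gq"], "father_gq": m["father_gq"],
    }


def _clean_dnm_record(rng, config, reference, site) -> dict:
    chrom, pos0 = site
    pos1, ref, alt = _alleles(rng, config, reference, chrom, pos0)
    return _record_from(chrom, pos1, ref, alt, _clean_metrics(rng, config))


def _decoy_record(rng, config, reference, genes, gene_list, intergenic,
                  ig_weights, mask, used, dtype, af_table):
    """A record violating exactly the targeted criterion, clean otherwise."""
    gene_id, region = None, "intergenic"
    if dtype == "blacklist":
        black = [g for g in gene_list if g.gene_id[:3] in ("HLA", "MUC")]
        if not black:
            return None, None, None
        g = black[int(rng.integers(0, len(black)))]
        site = _place_in_gene(rng, g, mask, used)
        gene_id, region = g.gene_id, "genic"
    elif dtype == "mappability":
        site = _place_in_mask(rng, mask, genes, used)
    else:
        site = _place_intergenic(rng, intergenic, ig_weights, mask, used)
    if site is None:
        return None, None, None
    chrom, pos0 = site
    seq = reference.sequence(chrom)
    ref_base = seq[pos0]
    alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(0, 3))]
    m = _clean_metrics(rng, config)
    if dtype == "ad_alt":
        m["child_dp"], m["child_alt"] = 20, 5  # AB 0.25 passes, AD 5 < 6 fails
    elif dtype == "child_gq":
        m["child_gq"] = 10
    elif dtype == "parent_gq":
        m["mother_gq"] = 12
    elif dtype == "parent_dp":
        m["father_dp"] = 8  # strict > 8
    elif dtype == "ab":
        m["child_dp"], m["child_alt"] = 40, 8  # AB 0.2, AD 8 >= 6
    rec = _record_from(chrom, pos0 + 1, ref_base, alt, m)
    if dtype == "pop_af":
        af_table[(chrom, pos0 + 1, ref_base, alt)] = 0.01
    return rec, gene_id, region


def _place_in_mask(rng, mask: MappabilityMask, genes: GeneSet, used, tries=50):
    chroms = [c for c, ivs in mask._ivs.items() if ivs]
    if not chroms:
        return None
    for _ in range(tries):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        ivs = mask._ivs[chrom]
        s, e = ivs[int(rng.integers(0, len(ivs)))]
        pos0 = int(rng.integers(s, e))
        # keep mask decoys out of gene footprints so only one criterion fires
        if genes.overlapping(chrom, pos0) or (chrom, pos0) in used:
            continue
        used.add((chrom, pos0))
        return chrom, pos0
    return None


def _truth_row(child_id, cohort, rec, gene_id, region, kind, target) -> dict:
    return {
        "child_id": child_id, "cohort": cohort, "chrom": rec["chrom"],
        "pos": rec["pos"], "ref": rec["ref"], "alt": rec["alts"][0],
        "gene_id": gene_id or "", "region": region, "kind": kind,
        "decoy_target": target,
    }


# ---------------------------------------------------------------------------
# VCF output


def write_family_vcf(family: Family, path: str | Path,
                     chrom_lengths: dict[str, int]) -> None:
    child = family.child_id
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{child}\t{child}_mo\t{child}_fa")
    for r in family.records:
        child_ad = ",".join(str(x) for x in r["child_ad"])
        child_f = f"{r['child_gt']}:{child_ad}:{r['child_dp']}:{r['child_gq']}"
        mo_ad = f"{r['mother_dp']},0" if r["mother_gt"] == "0/0" \
            else f"{r['mother_dp'] // 2},{r['mother_dp'] - r['mother_dp'] // 2}"
        fa_ad = f"{r['father_dp']},0" if r["father_gt"] == "0/0" \
            else f"{r['father_dp'] // 2},{r['father_dp'] - r['father_dp'] // 2}"
        mo_f = f"{r['mother_gt']}:{mo_ad}:{r['mother_dp']}:{r['mother_gq']}"
        fa_f = f"{r['father_gt']}:{fa_ad}:{r['father_dp']}:{r['father_gq']}"
        alt = ",".join(r["alts"])
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{alt}\t.\tPASS\t.\t"
            f"GT:AD:DP:GQ\t{child_f}\t{mo_f}\t{fa_f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
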