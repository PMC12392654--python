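# Methods

## Scope and model

The package implements a trio-based *de novo* mutation (DNM) analysis in
five layers: (1) a synthetic study generator; (2) Mendelian candidate
detection and hard filtering from per-family VCFs; (3) region/consequence
annotation against gene models, a reference sequence, and per-site
functional scores; (4) per-gene enrichment tests — case-only Poisson
(point-based, coding and CADD ≥ 15 noncoding; segment-based on 1 kb
constraint windows) and case-control carrier burden; (5) Fisher combination
of evidence across variant classes and cohorts with Bonferroni/BH
correction.

The core modelling assumption of the point-based noncoding test is that a
gene's noncoding footprint mutates at the same per-bp rate as its CDS, so
the coding expectation `p_g × n_trios × 2` scales by the ratio of noncoding
to coding target length. "Noncoding length" is, by default, the **count of
noncoding footprint positions with CADD ≥ 15** — the effective mutational
target that survives the CADD filter applied to observed DNMs — rather than
the raw footprint length. The raw-bp alternative (`nc_length_mode="raw"`,
paired with unfiltered noncoding counts) is retained for sensitivity
analysis; the two modes are identical in expectation up to the score-track
thinning fraction. The segment-based test replaces the gene-rate model with
window-specific backgrounds: `E(bin) = average_count_1kb × β`, where
`average_count_1kb` is the analyzed cohort's mean noncoding DNM count over
the bin universe and β is the window's expected rare-variant count over the
all-window mean.

## Filtering semantics

All eight filters are evaluated for every candidate and **all** violations
are recorded, enabling per-filter exclusion accounting. Boundary semantics,
fixed by the threshold definitions: child ALT-allele depth ≥ 6 (AD is read
as the ALT-supporting read count; a total-depth reading would make the
allele-balance filter redundant at low depth); child GQ ≥ 25; each parent
independently GQ ≥ 20 and DP **strictly** > 8; population AF < 0.001 with
missing AF treated as 0 (novel variants pass); allele balance in the
**closed** interval [0.25, 0.75]; zero-depth records fail with
`ab_undefined`. Children homozygous for the alternate allele are excluded at
the candidate stage (`child_hom_alt`) as implausible germline de novo
events. The gene blacklist matches symbol prefixes (HLA, MUC, configurable)
and applies to variants located *inside* a blacklisted gene's footprint —
not to intergenic variants merely assigned to one as nearest gene. The
100 bp same-gene collapse uses transitive (single-linkage) clustering; each
cluster keeps the highest-severity call (LGD > missense > other exonic >
ncRNA splicing > UTR > intronic > flank > ncRNA > intergenic), ties broken
by smaller position.

## Annotation conventions

Coordinates are 0-based half-open internally; VCF positions (1-based)
convert at the I/O boundary. The genic footprint is the transcript span
± 1 kb. Splicing means within 2 bp of an exon/intron boundary on the intron
side (canonical dinucleotides); for coding genes such calls are
likely-gene-disrupting (LGD), for noncoding RNAs they classify as
`ncRNA_splicing` and stay noncoding. Classification precedence across
overlapping genes is exonic > splicing > ncRNA exonic/splicing > UTR >
intronic > ncRNA intronic > flank > intergenic, ties by lexicographic gene
id. Consequences come from codon translation with strand handling; indels
with length ≢ 0 (mod 3) are frameshifts; LGD = frameshift
insertion/deletion, startloss, stopgain, stoploss, splicing. CDS lengths not
divisible by 3 flag the gene and yield consequence `other`. Score
thresholds: CADD ≥ 15 (inclusive), FATHMM-like > 0.5 (exclusive), SpliceAI
≥ 0.8 (inclusive); missing scores stay missing.

## Statistical conventions

`poisson_case_only(x, λ) = P(X ≥ x)`; zero observations give p = 1; p-values
are floored at 1e-300 before log transforms. Fisher combination uses
χ²(2k); with one input it is the identity. Odds ratios apply the
Haldane–Anscombe 0.5 only when a cell is zero (with no zero cells the plain
cross-ratio is returned exactly). Cross-cohort combination is hierarchical:
per-cohort combined p = Fisher(coding, noncoding); cross-cohort family p =
Fisher over cohorts within a family; the overall p Fisher-combines the
per-cohort combined p-values. BH q-values run over a declared test universe
(all genes in the rate table for simulated cohorts; 20,000 genes is the
exome-wide default), within each test family separately; Bonferroni
significance is flagged at raw p < 2.5 × 10⁻⁶. For segment tests over a
restricted bin universe, β is renormalized within the analyzed universe
(flag-controlled, default on): β's defining normalization (mean 1 over all
windows) cannot hold over a subset, and renormalizing restores the property
that summed expectations conserve the observed total under single-assignment
mapping. Bins overlapping several genes are assigned to all of them by
default (marginal per-gene tests); `single_assignment` picks the
longest-overlap gene.

## The synthetic study generator

The generator emulates the study conditions at reduced genomic scale: the
simulated gene set stands in for the exome, so the per-child **coding** DNM
mean (default 1.27) and the genome-wide per-child DNM mean (default 90) are
spread across the simulated genes, keeping per-trio summary statistics at
the real-cohort scale. Per child the total DNM count is Poisson; each DNM
falls in gene *g* with probability ∝ `2 p_g × footprint/CDS-length ×
enrichment fold` (case arm only) and in intergenic space with the remaining
mass, uniformly within the chosen region — exactly the uniform-mutability
assumption the point test makes, so planted counts are Poisson with the
tests' model expectations and null calibration is meaningful end to end.
Gene mutation rates are coding length × a log-normal gene factor (σ = 0.25),
normalized to the configured per-child coding mean; this reproduces the
strong length–rate correlation (r ≈ 0.9) that motivates length-scaled
expectations. Per-site scores come from a stateless counter-based hash of
(seed, stage, chromosome, position), so the CADD-like track is deterministic
and lazily evaluable over arbitrarily large coordinates; 1.8% of positions
lie at ≥ 15 by construction, mirroring the tail the threshold selects.
Window expected-rare-variant counts are Gamma(4, 0.25) (mean 1, realistic
heterogeneity). Read-depth metrics: DP ~ NegBin(mean 30), ALT reads ~
Binomial(DP, ½) clipped into the clean acceptance region (so engineered
decoys, not sampling noise, exercise the filters); clean child GQ ≥ 40,
parent GQ ≥ 40, parent DP ≥ 12. Decoys violate exactly one criterion each
and are truth-labelled with the targeted reason. Inherited heterozygous
background variants (with population AFs) exercise the candidate stage.
Planted sites are unique cohort-wide (no recurrent sites), so a clean DNM
can never collide with another family's background variant in the AF table.

One global integer seed drives a named PCG64 stream per stage, making all
outputs byte-identical under a fixed config and insulating stages from one
another.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequence-context mutational signatures (CpG),
read-level errors and mosaicism, overlapping genes and multiple transcripts,
sex chromosomes (all expectations use the autosomal ×2), relatedness and
ancestry structure, and recurrent sites.

## Validation experiment sizes

Chosen once, as the package's own design:

- **Null calibration**: 500 case trios × 600 coding genes with long
  (~180 kb) noncoding footprints and per-gene expected noncoding counts
  averaging a few hundred. Poisson tail p-values are discrete with atom
  spacing ≈ pmf at the mode ≈ 1/√(2πλ); a two-sided KS test against U(0,1)
  at n = 600 genes resolves deviations ≳ 1.63/√600 ≈ 0.07, so per-gene λ
  must be large for the KS check to measure calibration rather than
  discreteness. This run uses the raw-length noncoding mode end to end
  (generator → VCF-equivalent records → caller → annotator → point test);
  CADD thinning is Poisson-preserving and is exercised at smaller scale
  elsewhere.
- **Recovery**: 20 replicates of 200 genes × 500 trios; the two
  highest-rate genes get 10× enrichment (cohort expectations ≈ 2.8–3.3) and
  must rank in the coding top 5 (rank = 1 + number of strictly smaller
  p-values).
- **Filter accounting**: 20 trios, 30 genes, ~4 decoys per child across all
  eight filter types, through a full VCF write/read round trip.
- **Conservation**: 20 trios, 25 genes, 600 bins; single-assignment mapping
  in both genic and intergenic modes must conserve observed totals to
  1e-9 relative.

## Known limitations

Real cohorts violate the uniform per-gene mutability assumption
(sequence-context effects are exactly why the segment test exists); the
point and segment tests share DNM calls, so their combined evidence is not
independent in the Fisher sense; multi-transcript genes are collapsed to
exon/CDS unions; the per-position score model is marginal (no local
correlation), which makes the simulated CADD ≥ 15 mutational target slightly
smoother than a real track; and the burden fold change is carrier-based by
default, with a count-based mode provided because published fold changes are
not always reproducible from subject counts alone.
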