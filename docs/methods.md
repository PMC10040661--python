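# Methods

## Scope and data model

The package implements the computational stages of a cultivar pan-genome
study as a library: QC filters, PAV calling and classification, a
fixed-difference divergence scan, and heterozygosity/LD statistics.
Genotypes are diploid biallelic SNP calls coded 0 (hom-ref), 1 (het),
2 (hom-alt), −1 (missing) in a loci × cultivars matrix; all coordinates
are 1-based inclusive (VCF/GFF3 convention), and any half-open arithmetic
is internal to the function that needs it. Standard formats go through
established parsers (cyvcf2 for VCF, gffutils for GFF3, Biopython for
FASTA/FASTQ); tabular interchange (PAV CSV, panel TSV, hit TSV) uses
pandas.

## Filters

Reads are discarded when they contain a run of more than three Ns, more
than three bases at PHRED ≤ 20, a median PHRED below 20, or fall under the
library-class length floor (50 bp paired-end, 25 bp mate-pair). Reasons
are recorded per read in that order of checks. Note the median rule is
mathematically implied by the low-quality-count rule for any read of
eight or more bases, so the count rule is what fires in practice; the
median check is retained so the stated rule set is complete. Transcripts
shorter than 241 bp are removed by default; the neighbouring convention of
a 240 bp floor is available via `min_len` since both readings circulate.
Non-reference contigs must exceed 1,000 bp.

The contamination screen gates hits per hit (E-value < 10⁻⁸, length
> 100 bp, identity > 70%) and then unions the surviving intervals.
Union rather than summation is the only aggregation bounded by the contig
length (overlapping hits cannot push the fraction past 1), which is why
"aggregated matches > 25% of length" is computed that way. All thresholds
are strict inequalities and configurable.

## PAV calling and classification

The coverage-threshold caller marks a gene absent in a cultivar when the
fraction of its exon bases covered (at the caller's depth floor, default
2×) is below `lost_cutoff` = 0.2 — the customary defaults of
exon-coverage gene-loss callers; both are parameters. Classification is a
pure function of carrier count (see README); category counts always
partition the gene set and this is asserted on every run. Reported
percentages are rounded half away from zero to one decimal, with
two decimals below 1% — the convention that reproduces every published
one-decimal figure this package emulates. Mean contig lengths similarly
round to the nearest integer. Accumulation curves default to the mean ±
SD over 100 seeded random cultivar orderings since no canonical ordering
exists; an explicit order is also accepted.

A pooled contig summary appends a raw-sum `Total` row. Published pooled
totals may instead describe a de-duplicated contig set; de-duplication
requires an explicit mapping and is deliberately not guessed, so both
views can be reported side by side when a dedup map exists.

## Divergence scan

The locus rule requires one subpopulation fixed hom-ref and the other
fixed hom-alt, each side independently tolerating at most one het and no
opposite homozygote — the literal per-subpopulation reading of the
"maximum of one heterozygote cultivar" tolerance. Missing data defaults
to `exclude_locus` (a locus with any uncalled cultivar in either
subpopulation is ineligible) because fixation cannot be asserted for
uncalled cultivars; `ignore_missing` with a minimum called fraction of
0.8 is the permissive alternative. Orientation (which side carries the
reference allele) is recorded.

Selected loci within `merge_gap` of each other on a chromosome merge into
one region. No published grouping rule exists for turning selected loci
into regions, so the gap rule is an explicit, documented stand-in; the
150 kb default keeps a ~135 kb cluster of four loci as a single region
while leaving isolated loci as single-position regions, and the gap is
always reported with the output. Merging is idempotent, order-independent,
and the region count is non-increasing in the gap.

Nearest-gene distance is 0 on overlap, otherwise the gap between nearest
interval ends; ties break to the smaller gene start. The within-region LD
check computes all pairwise r² among member SNPs and passes when the
minimum exceeds 0.95 (strict).

## Heterozygosity and LD

Heterozygosity is the per-individual proportion of called genotypes that
are heterozygous (missing excluded from the denominator); subpopulation
values are unweighted means over members. A distributional statistic is
deliberately not implied — the per-individual proportion is the definition
here and feeds the subpopulation contrast directly.

r² is the squared Pearson correlation of genotype dosages over the
cultivars called at both loci — composite LD, the standard phase-free
estimator for unphased SNP matrices. Pairs with a locus monomorphic in
the shared called set are undefined and excluded from curves. Decay
curves use all same-chromosome pairs within `max_dist` (default 1 Mb),
subsampled to at most 500,000 seeded pairs for large inputs, and are
smoothed by a degree-2 local polynomial with tricube weights evaluated on
a 100-point grid. The span (default 0.3) has no canonical value and is
recorded in outputs; the smoother is implemented directly because the
commonly available lowess routines are degree-1, and it reproduces exact
quadratics to machine precision (tested).

## Synthetic data

The generators emulate the study panel's structure, not sequence realism:

* **PAV**: quota sampling fixes the realized category composition exactly
  (the default 81.3 / 1.8 / 4.3 / 12.6% split over 31,016 genes), rather
  than per-gene Bernoulli draws, so classification tests are
  deterministic. `donor_bias` (default 0.972) sends a specific or
  dispensable gene's carriers to the two donor cultivars
  (Taishanhong/Tunisia), else to the non-donors. A fully deterministic
  variant, `pomegranate_pan_composition`, realizes the published
  composition to the gene (30,667 donor-pair union; 198 added by
  Purpursid; 151 by the remaining eight).
* **Genotypes**: two chromosomes (40 and 25 Mb), 2,500 loci each, 20
  soft / 19 hard cultivars, shared per-locus allele frequencies
  (uniform on 0.05–0.95), per-subpopulation het rates 0.12 (soft) and
  0.30 (hard) — the hard-seeded group is the high-heterozygosity one —
  and 2% missing calls, masked after planting. Twelve planted
  fixed-difference loci (a four-locus cluster spanning ~140 kb plus eight
  isolated loci) are hom-ref in soft and hom-alt in hard before masking.
  LD comes from a copying model: a latent allelic chain per cultivar
  copies the previous locus' state with probability exp(−d/L), default
  L = 50 kb — a one-parameter decay that is oracle-checkable
  (independent loci at L = 0; monotone decay otherwise). Heterozygous
  calls are overlaid per (cultivar, locus) at the subpopulation rate, so
  per-individual heterozygosity equals the parameter directly while
  homozygous dosages carry the spatial correlation.
* **Reads/contigs**: planted read failures each violate exactly one read
  rule (an N-run, four Q20 bases, a 40 bp read); a median-only failure is
  not plantable because it implies the count rule (above). Planted
  contaminants carry two overlapping passing hits whose union covers 40%
  of the contig.

What passing tests show, and do not: recovery results demonstrate the
*rules* are implemented exactly (precision = recall = 1 against planted
truth is a property of noise-free plantings, not a field expectation);
they say nothing about alignment error, reference bias, coverage
dispersion or population structure in real panels, none of which the
generators model.

## Numerical choices and degenerate inputs

Half-away-from-zero rounding (with a magnitude-scaled epsilon against
binary-float noise) for all reported percentages and means. Monomorphic
loci yield NaN r² and are excluded rather than zero-filled. Regions with
fewer than two members return "not applicable" from the LD check. A
cultivar with zero called genotypes is flagged and excluded from its
subpopulation mean. Empty reads fail the length rule. LD smoothing is
skipped (with a warning) below three raw pairs; loess windows with fewer
than three distinct x-values fall back to a weighted mean.

## Problem sizes

Defaults are desk-scale: the 31,016 × 11 composition matrix and
5,000-locus × 39-cultivar panels run the full simulate → qc → pav →
classify → scan → ld chain in seconds on one core, and the test suite in
well under a minute. All sizes scale via the sim specs.

## Known limitations

The PAV caller consumes precomputed exon-coverage tables (it does not
read BAMs); the scan implements only the fixed-difference rule (no FST or
haplotype statistics); LD is composite r² (no D′ or phased r²); the
contig summary does not perform CD-HIT-style de-duplication. These match
the package's scope of re-usable pipeline stages around standard external
tools.
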