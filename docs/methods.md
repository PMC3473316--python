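# Methods

## Model of the data

A *pool* is a sequencing library prepared from mixed RNA of several genotypes
of one population group. Reads sample the pool's allele frequencies: at a
site where the alternate allele has frequency *f* in the pool's transcript
mass, each read covering the site carries the alternate with probability *f*,
independently. All frequency estimation in this package is read-level (the
number of genotypes behind a pool is not modelled; the generator exposes
arbitrary per-pool frequencies instead of genotype mixtures, since equal-mass
RNA pooling makes the read-level frequency the natural observable).

Coordinates are 1-based inclusive everywhere in inputs and outputs; internal
0-based arithmetic is never exposed.

## Read cleaning

Four parameters with defaults: more than `max_missing = 2` 'N' calls
discards a read; head mean quality below 15 over the first 10 bases discards
it; the 3' tail is trimmed while the trailing-window (10 bp) mean quality is
below 20, with the cut point refined by removing any remaining trailing bases
individually below the threshold (iterated to a fixpoint, which makes
cleaning idempotent and prevents a kept read from ending in a sub-threshold
run); reads shorter than 30 bp after trimming are dropped. Rule order is
missing/head check → 3' trim → length filter. The trailing-window width is a
realization choice (the underlying rule is stated only as "3' regions with
low mean quality") and is configurable.

## Calling

Only columns with depth ≥ `min_coverage` (6) are mined. Depth counts
contributing reads: primary, mapped, non-duplicate alignments with mapping
quality ≥ 1; 'N' bases and quality-0 bases are excluded entirely. An allele
is *supported* at ≥ `min_allele_reads` (3) reads. With two or more supported
alleles the column is called polymorphic if the *call quality* — the minimum
over non-majority supported alleles of the summed Phred quality of their
supporting bases — reaches `min_quality` (70); otherwise the column is
demoted to a monomorphic call on the majority allele. Columns with exactly
one supported allele are monomorphic calls with no quality test. The quality
rule is what separates true minor alleles from sequencing errors at pooled
sites: three genuine bases at ~Q30 sum to ~90, while error bases carry low
qualities and cannot reach 70.

Call quality is defined this way because the upstream pipeline this mirrors
used an internal, undocumented per-SNV quality; the realization here uses
only pileup-observable quantities and is configurable. Majority ties break
lexicographically. Insertions are represented as composite alleles
`<anchor base>+<seq>` at the anchor column and deletions as
`<anchor base>-<length>`, with deleted columns receiving nothing from the
spanning read — so column depth always equals the number of contributing
reads. A variant is an INDEL if any supported allele is composite, else SNP.

Monomorphic ≥ 6X columns are kept as plain per-position calls rather than
compressed runs; at the scales this package targets the simple representation
is preferable and keeps the merge logic transparent.

Merging emits a record where ≥ 2 distinct alleles are supported across pools
combined, or a non-reference allele is fixed in some pool. Pools without a
≥ 6X column at the position are recorded as `no_coverage` and excluded from
that position's pairwise statistics. Global MAF uses summed supported depths
across pools; pool MAF uses the pool's supported depths (ties give 0.5 for
biallelic sites by arithmetic).

## Annotation and densities

Gene models come from GFF3 (gene/mRNA/exon/CDS/five_prime_UTR/
three_prime_UTR); introns are the inter-exon gaps; models whose CDS falls
outside exons are rejected with a warning. A variant is tested against CDS,
then UTR, then intron of each overlapping gene; a variant overlapping several
genes counts once per gene in per-gene statistics and once in genome-wide
totals. The distance to the nearest exon-intron junction is measured to the
exonic edge base of the intron. Feature densities divide variant counts by
the ≥ 6X coverage mask (union over pools) intersected with feature intervals;
using the same mask for lengths and counts keeps densities comparable across
features. UTR5 and UTR3 are merged as "UTR" for reporting.

## Diversity statistics

"Shared" between two pools means polymorphic within both (not merely
detected in both). "Fixed" means exactly one supported allele — a second
allele below 3 reads (e.g. scattered errors) does not break fixedness.
Fixed-differential requires both pools fixed, for different alleles. The MAF
histogram uses right-closed 0.05 bins over [0.5, 1.0] (binning is a
presentation choice). The MAF < 0.7 count/percentage uses pool-polymorphic
SNPs only.

## Marker filters and panel selection

"Closer than 60 bp" is read strictly for both IS60 and CS60: distance < 60
flags, exactly 60 passes. CS60 neighbourhoods count all SNVs, including
INDELs, as flagging neighbours (any variant disturbs primer design).
CS60_MAF(t) ignores flanking variants whose *global* MAF is ≥ t, so rare
flanking alleles are tolerated; lowering t enlarges the pass set
monotonically. A per-pool MAF option is not provided since the filter is a
collection-level property. Panel candidates must pass VKS, IS60 and
CS60_MAF(t), be fixed within every `monomorphic_within` pool, show a fixed
difference across every `polymorphic_between` pair, and respect an optional
global-MAF ceiling; `n_select` are drawn uniformly without replacement from a
seeded generator. "Variable in all groups" in the filter table means
polymorphic in all pools (the alternative MAF-based reading is available by
filtering the records directly).

PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ², computed on collection-wide read-frequency
estimates; it never exceeds the expected heterozygosity 1 − Σpᵢ².

## Synthetic data

The generator's defaults define the study conditions: 3 scaffolds × 22 kb,
6 genes per scaffold with 4 exons of 450 bp (introns 150 bp, UTRs 120 bp,
32.4 kb of exome), 8 pools, 49 bp reads at 30X mean coverage, 1%
substitution error, 0.5% missing calls. Planted classes and default counts:
60 shared-across-all (f = 0.5 in every pool), 40 pool-specific (f = 0.5 in
one pool, rotating), 30 fixed-differential (f = 1 in pool 1, 0 elsewhere,
pair (1, 8)), 40 background (random per-pool frequencies), 20 near-intron
sites 20–59 bp from a junction, 15 clustered pairs 10–60 bp apart whose
partners cycle through frequencies 0.5/0.1/0.05 (so flanking-MAF filters have
non-trivial work), and 15 short indels. All other sites keep ≥ 61 bp mutual
spacing and ≥ 61 bp distance from exon edges, separating filter effects from
coverage edge effects.

Reads are placed uniformly within single exons — never across junctions —
emulating unspliced cDNA-to-genome alignment; intron coverage is exactly
zero. Per-exon read counts are Poisson with mean `depth · exon_len /
read_len`, so mean exon coverage matches the target while exon edges and
introns provide genuinely sub-6X territory. Base qualities follow a two-level
model: body ~Q34 ± 3 with a 3' ramp losing 8 points over the last 10 bases;
substitution-error bases are assigned low qualities (Q12–22), realizing the
Phred quality/error correlation that the calling quality threshold exploits;
missing calls are 'N' at Q0 (the base-space proxy for missing colorspace
calls). Paired ends, splice junctions, colorspace chemistry and library
normalization effects are not modelled, so passing tests demonstrate the
correctness of the rules under idealized error structure — not performance on
real SOLiD data, where mapping artefacts and correlated errors would lower
precision.

Determinism: every stage derives its generator from `(seed, stage)` or
`(seed, 100 + pool)` tuples, so identical seeds give byte-identical outputs
and each pool is independently reproducible.

## Problem sizes and numerical choices

The bundled test suite and the acceptance script run the full pipeline on the
default 32.4 kb exome (≈ 160 k reads across 8 pools), a size chosen so a
complete simulate→clean→call→annotate→diversity→select-panel cycle finishes
in well under a minute while still yielding ≈ 1200 (site, pool) MAF
estimates for calibration. Recall/precision guarantees (≥ 0.95) are evaluated
over planted sites with a per-pool frequency in [0.2, 0.8] or fixed
differentials; rarer alleles (the 0.05/0.1 clustered partners) fall below the
3-read support floor by design. MAF calibration uses (site, pool) pairs with
planted 0 < f < 1 and asks for agreement within 3 binomial standard
deviations at the observed depth; truly fixed sites are excluded because
their binomial SD is zero and any single sequencing error would fail them.

## Known limitations

* The caller has no genotype-likelihood model; it is a thresholded tally, as
  intended — its statistical behaviour is inherited from the thresholds.
* Deletion-spanning reads contribute no evidence at deleted columns, slightly
  depressing depth inside deletions.
* Multi-allelic sites estimate MAF as max-depth/total-depth, which can fall
  below 0.5 for three supported alleles; the histogram clamps such values
  into its first bin.
* The QC stage operates on the FASTQ mirror of the simulated reads; the SAM
  alignments are consumed as given (mapping is out of scope), so trimming
  does not feed back into calling.
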