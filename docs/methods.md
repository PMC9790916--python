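# Methods

This note records the models, conventions and numerical choices behind
`circseq`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and formats

All coordinates are 0-based half-open internally (BED convention). The GTF
writer/reader converts to 1-based closed on disk; BED6/BED12 are written
as-is. Minus-strand junctions are stored in genome coordinates with
`start < end`, so span arithmetic and interval overlap never depend on
strand. Matrices are TSV with a feature-id index column and one column per
sample; float matrices are re-read with round-trip parsing so cached
pipeline stages reproduce downstream outputs bit for bit.

## Back-splice detection

The detector re-implements the anchor/extend strategy at desk scale,
replacing a genome-scale aligner with an exact k-mer index of the toy
genome (anchor length 20 nt by default, the common convention). For each
read, the terminal anchors are looked up on both strands; a placement pair
on one chromosome in inverted genomic order is a candidate back-splice. Both
anchors are then extended toward the read interior against the genome and
the total mismatch count `edit(b)` is evaluated for every interior
breakpoint position `b`. Definitions:

- `edit` — the minimum of `edit(b)` over positions (candidates with
  `edit > 2` are discarded at detection time);
- `breakpoint` — the number of positions attaining that minimum. A junction
  whose flanking bases repeat (`genome[start] == genome[end]` or
  `genome[start-1] == genome[end-1]`) can slide and yields `breakpoint >= 2`;
- `anchor_overlap` — the genomic overlap of the two extended alignments
  (nonzero only when the span is shorter than the read);
- `qual_A`/`qual_B` — an anchor uniqueness margin scaled to [0, 40]:
  `round(40 / occurrences)` over both strands, so 40 means a unique anchor
  and the `> 35` filter clause passes only for uniquely placed anchors.

A read that matches the genome contiguously is colinear and never reported.
Reads shorter than twice the anchor are skipped and counted in a warning.
Each read reports at most one candidate (the minimal-edit closure, with a
deterministic coordinate tie-break).

Aggregation to junctions takes per-sample read counts, distinct read ids
(`n_uniq`), per-junction maxima of the anchor qualities, the best (minimum)
`edit` and `anchor_overlap`, and the worst (maximum) `breakpoint` — one
ambiguous supporting read flags the whole junction, which is the
conservative reading of the breakpoint clause.

The eight reliability clauses are applied as a conjunction with one internal
disjunction (either anchor quality suffices). Both unique-read clauses —
`n_uniq > 2` and `n_uniq > floor(samples/2)` — apply by default and are
independently switchable, since recipes differ on whether they are joint or
alternate. "Length" is the genomic span `end - start`, not the spliced
length. `floor(samples/2)` counts the samples in the dataset being filtered.

Origin classification: a junction is *exonic* when both endpoints coincide
with exon boundaries of one same-strand gene (spliced length = sum of the
enclosed exons); any other gene overlap is *intronic*, hosted by the gene
with the largest overlap (lexicographic tie-break); otherwise *intergenic*.
Precedence exonic > intronic > intergenic makes spans touching several genes
classify deterministically rather than erroring.

## Quantification and differential screening

RPM is `1e6 * C / N` per sample on back-spliced read counts; columns sum to
1e6 by construction and an all-zero sample is a hard error naming the
sample. RPM is reporting-only: the exact test runs on raw counts, as count
models require.

Normalization factors are depth-like and gmean-normalized. `librarysize`
returns column totals over their geometric mean. `tmm` returns the weighted
trimmed mean of per-feature log2 ratios of raw counts against a reference
sample (the one with the median total), trimming 30% per tail of M and 5%
per tail of A, with inverse-variance weights `1/obs + 1/ref`; this is a
robust relative depth that ignores a minority of composition outliers.
Effective library sizes are `factor x gmean(totals)`.

The exact test scales counts to a common library size (geometric mean of
effective sizes), rounds, and pools within groups. Under the null the two
group sums are independent negative binomials with a common per-sample mean
and sizes `n_g / phi`, so the conditional law of one sum given the total is
negative hypergeometric; the two-sided p sums the probabilities of all
splits no more likely than the observed one (minimum-likelihood convention,
with the customary `1 + 1e-7` guard against float ties). At `phi = 0` this
reduces to the binomial split test. `dispersion="auto"` uses a
method-of-moments common dispersion, pooling `(var - mean) / mean^2` across
features weighted by residual degrees of freedom and flooring at 0 — a
deliberate simplification (no empirical-Bayes shrinkage, no tagwise
estimates). Fold changes use normalized group means with a pseudo-count of
0.5 so zeros stay finite. Features with zero counts in both groups report
`p = 1`, `log2FC = 0` rather than erroring.

Screening is the strict printed rule — `log2FC > 1` or `< -1` **and**
`p < 0.05` on raw p-values; the emitted BH-FDR column is a side channel, not
part of the screen. With 600 features this rule admits a visible tail of
false positives by design; calibration is checked instead by the type-I
property below.

`2^-ddCt` is the plain closed form on four finite Ct values.

## Enrichment

One-sided upper-tail hypergeometric over-representation:
`p = P(X >= k)`, `X ~ Hypergeom(N, K, n)`, computed via the survival
function. The universe is the set of genes carrying at least one annotation
in the collection under test (not all genome genes); candidate genes outside
it are dropped with a logged count. Host genes come from non-intergenic DE
circRNAs, deduplicated. Rankings use raw p (ascending, ties by set id) with
a BH column alongside; flat set membership only, no ontology-graph
propagation.

## ceRNA screening

Spearman is computed as the product-moment correlation of average ranks,
with exact +/-1 short-circuits for perfectly (anti)monotone rank vectors and
a two-sided p from the t approximation on n-2 degrees of freedom (it matches
`scipy.stats.spearmanr` to machine precision elsewhere). Pearson uses
`scipy.stats.pearsonr`, whose beta-distribution p is mathematically the same
t test. Constant vectors and n < 3 are errors, not NaNs.

A triad (circ, miR, mRNA) is emitted iff the molecules are
targeting-compatible (`miR in circ_to_mir[circ]`,
`mRNA in mir_to_gene[miR]`) and all three correlations carry the sponge
signs and pass their thresholds. Published cut-offs are not stated anywhere
authoritative, so the defaults are the weakest faithful reading: sign plus
`p < 0.05`, with magnitude cut-offs exposed as configuration. Targeting
relations are an input table; the bundled toy seed-match generator
(reverse-complement of miRNA positions 2–8) exists only for self-contained
demos. The network is the union of circRNA–miRNA and miRNA–mRNA edges with
node types and correlation attributes; SIF, node/edge TSV and GraphML
exports round-trip through the module's own readers.

## Synthetic data: what it emulates

The generator mirrors the four-group DRG design: DR-Exp/DR-Sham (central
axon injury) and SN-Exp/SN-Sham (peripheral), three replicates per group by
default — replicate count and depth are configuration, since sequencing
studies rarely print them. Defaults and their rationale:

- **Genome**: 4 chromosomes x 250 kb, 200 non-overlapping genes of 3–6
  exons (150–300 nt) separated by 200–800 nt introns. Small enough for
  exhaustive anchor search, large enough that 20-mers are effectively
  unique.
- **circRNAs**: 600 events, exonic/intronic/intergenic apportioned
  66/16/18 by largest-remainder (deterministic, sums exactly). Exonic spans
  run between exon boundaries of one gene; intronic spans sit strictly
  inside one intron; intergenic spans avoid genes. All spans are below the
  100 kb filter ceiling and above the read length, and junctions whose
  flanks would allow sliding are rejected at planting so the truth is
  recoverable at `breakpoint == 1`. Keeping planted DE features a small
  minority of the catalog matters: normalization assumes most features are
  unchanged, as in real catalogs where tens of DE circRNAs sit in a
  catalog of thousands.
- **Planted effects**: the central contrast plants 9 up + 24 down, the
  peripheral 32 up + 23 down, at |log2FC| = 2 on disjoint feature sets.
  Planted features sit at a baseline mean of 100 back-spliced counts so
  that, per the package's own power analysis, the strict screen has
  per-feature power above 99% in both directions at 3 vs 3 and dispersion
  0.1; background features draw lognormal means (median 10), matching the
  low abundance of most circRNAs. Typical recovery is 95–100% per
  direction; at three replicates an occasional planted feature lands within
  the |log2FC| <= 1 band by sampling alone.
- **Reads**: junction reads are tail-of-span followed by head-of-span
  (reverse-complemented for minus-strand events), with the junction offset
  uniform inside the read and Poisson/NB per-sample coverage (mean 6);
  colinear background reads are exact genome substrings. Substitution
  errors are optional and off by default; there is no quality-trimming or
  paired-end model.
- **ceRNA triads**: each planted triad ties a varying circRNA profile `z`
  to `miR = 50 - 10(rho z - sqrt(1-rho^2) eps)` and
  `mRNA = 50 + 10(rho z + sqrt(1-rho^2) eps')`; at `rho = 1` the sample
  Spearman correlations are exactly -1 and the Pearson exactly +1. Decoy
  targeting edges with independent expression exercise the screen's
  rejection path.
- **Gene sets**: every gene receives 1–3 random set memberships (so the
  annotation universe covers the genome); one set per contrast is
  additionally stuffed with up to 12 host genes of that contrast's planted
  DE circRNAs, making it recoverably over-represented.
- **Determinism**: one global seed is split into independent per-artifact
  streams (genome / placement / reads / counts / ceRNA), so regenerating
  one artifact leaves the others untouched and all outputs are
  byte-identical for a fixed seed.

What passing tests on this generator do **not** show: performance on real
reads (no adapter/quality artifacts, no multi-mapping beyond anchor
collisions, no GT/AG splice signals), edgeR-equivalence of the exact test on
real overdispersed data (the dispersion model here is a single common
value), or database-dependent enrichment results (set collections are
synthetic). The study's real-data counts (a catalog of 2,310 circRNAs; 33
and 55 DE after central and peripheral injury) require the deposited
sequencing data and are deliberately out of scope; the presets reproduce the
*structure* of those results (9/24 and 32/23 planted), not the numbers from
real reads.

## Problem sizes

Defaults keep every stage interactive on one CPU: the full default pipeline
runs in a few seconds; the acceptance script (two pipeline runs, a
2,200-feature DE calibration, exhaustive hypergeometric enumeration to
N = 12, and a 200-fold permutation null) completes in under ten seconds.
These sizes are the package's chosen benchmark conditions; all of them scale
up through configuration.
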