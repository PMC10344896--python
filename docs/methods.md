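# Methods

This note records the models, conventions and design choices behind
`omniindel`, including where the behaviour was genuinely open and how the
synthetic study conditions were chosen.

## Variant model and normalization

A site is an InDel when at least one alternate allele differs in length
from the reference allele. Multi-allelic sites are kept as single records
with per-alt signed length changes; the size class is determined solely by
the largest absolute change, and the type is INS when all nonzero changes
are positive, DEL when all are negative, and MIXED otherwise. SNP alleles
co-occurring at an InDel site contribute a zero change and are ignored by
the classifiers.

Size classes use half-open intervals [1,3) SOI, [3,50) MOI, [50,1000) LOI,
[1000,∞) HOI. Published range conventions for these classes overlap at
their shared endpoints; a half-open partition is the only convention that
classifies every length exactly once, and it is applied uniformly at 3, 50
and 1000.

All records are left-aligned and trimmed to a minimal representation with
a single anchor base before any coordinate-based analysis (SSR overlap,
flank extraction, window grouping): trailing bases shared by all alleles
are stripped, borrowing the preceding reference base whenever an allele
would empty — which walks deletions and insertions to the left edge of any
repeat run — and then leading shared bases are stripped down to one
anchor. The operation is idempotent and its fixed point is the stored
form; positions are 0-based half-open internally and 1-based in all VCF
and table output. The *affected interval* of an anchored record runs from
the base after the anchor to the end of the reference allele; a pure
insertion has a zero-width interval at its insertion point.

Per-site statistics are computed over non-missing diploid calls only. A
genotype with either allele missing counts as a missing sample. MAF is
the frequency of the second-most-frequent observed allele — the minor
allele at a dimorphic site — which degrades gracefully at multi-allelic
sites. A site with all calls missing carries NaN MAF and is flagged.

SyRI-style structural-variant tables are read positionally (12-column
headerless layout, annotation type in column 11); only INS and DEL rows
become records, with lengths taken from the reference span (DEL) or query
span (INS). Copy-gain/loss and all other annotation classes are ignored.

## SSR scanning

The scanner finds maximal perfect tandem runs of 1–6 bp motifs with
minimum copy numbers 10, 6, 5, 4, 3, 3 for motif lengths 1–6 — the common
MISA parameterization for crop genomes. Runs are detected per period from
the match profile s[i] = s[i+p]; a maximal match run of length L spans a
periodic stretch of L + p bases containing ⌊(L+p)/p⌋ full copies. Only
full copies count; a run is reported at its shortest period (an AT run is
never also an ATAT run), with the lexicographically smallest motif
rotation as the canonical motif. Reverse-complement motifs are *not*
merged (AAG and CTT stay distinct), mirroring single-strand MISA
behaviour. N breaks runs; characters outside ACGTN are an error.
Imperfect and compound repeats are out of scope.

An InDel is classified against the scan as NON_SSR, SSR_OVERLAP (its
affected interval shares a base with a locus; insertion points touching a
locus boundary count, since an insertion at the array edge is biologically
part of the array) or SSR_MOTIF_CONSISTENT (additionally, every
length-changing allele inserts or deletes a whole number of copies of
some rotation of the locus motif). The two-tier split is deliberate:
overlap alone is what genome-wide overlap counts measure, while motif
consistency is what makes the allele series behave as an SSR ladder; the
summary reports both rather than guessing which a downstream user wants.

## Perfect InDel filter

Criteria are applied in a fixed order — length in [3,10] bp, dimorphic,
at least one single-copy 30-bp flank, MAF ≥ 0.05 (inclusive) — and the
verdict records the first failure, so verdict labels are reproducible and
the funnel is auditable. Flank copy number is the number of exact
occurrences of the 30-mer in the genome counting both strands (forward
hits plus reverse-complement hits; the source locus itself counts once).
Exact matching is deterministic and strictly conservative relative to an
alignment-based (BLAST) screen with mismatches; an optional
edit-distance-1 neighborhood mode (`strict_neighborhood`) is stricter
still. Flanks truncated by a contig end, or containing N, are treated as
ambiguous and can never certify uniqueness. Flanks shorter than 12 bp are
refused outright: exact-match counts on very short words are dominated by
chance hits.

## Multi-InDel panel design

The pipeline applies, in order: the candidate filter (dimorphic, 3–10 bp,
MAF strictly > 0.1, missing rate strictly < 0.5 — note the deliberate
asymmetry with the Perfect filter's inclusive MAF ≥ 0.05, matching the two
stated thresholds), greedy left-to-right window grouping, the subset-sum
distinctness test, and the spacing filter. Grouping starts at each
ungrouped leftmost candidate and extends while the reference span (first
member's affected start to last member's affected end) stays within
200 bp and the group has at most 5 members; groups of ≥ 3 are emitted and
their members consumed, otherwise the window advances by one candidate.
This makes grouping deterministic and single-pass; members beyond the
5-member cap remain available to seed later groups.

Haplotype-length distinctness is tested by direct enumeration of all 2^k
subset sums with early collision exit; k ≤ 5 by construction, so
enumeration is exact and cheap. A pairwise-comparison implementation over
all 2^k × 2^k pairs is kept alongside as an oracle-grade cross-check.

The spacing rule removes *both* members of any adjacent pair of accepted
clusters whose gap (next span start minus previous span end) is ≤ 200 bp.
The symmetric rule is order-independent; an asymmetric keep-one rule
cannot be justified from the stated conditions, and published counts
around this step are internally inconsistent, so the unambiguous
symmetric reading was chosen.

## Germplasm analysis

The genetic distance is an allele-sharing dosage distance, d(i,j) =
mean over shared non-missing loci of |xᵢ − xⱼ|/2, so d ∈ [0,1] with 0 for
identical genotypes and 1 for opposite homozygotes everywhere. The
metric behind the originally used distance package is not specified
anywhere reproducible, so this simple substitute is declared and the
distance function is pluggable. Missing data is handled by pairwise
deletion; pairs with no shared locus are flagged undefined and refuse
tree building.

UPGMA is implemented directly (average linkage with cluster-size
weighting, node height = merge distance / 2) rather than through a
library call so that tie-breaking is fully specified: among equal-distance
pairs the lexicographically smallest pair of cluster labels (each cluster
labelled by its smallest member id) merges first, and children are
ordered by label. scipy's average-linkage cophenetic matrix serves as an
independent oracle in the tests. On an ultrametric input matrix the tree
reproduces the input exactly as cophenetic distances. Trees are cut into
k clusters by repeatedly splitting the highest internal node.

PCA mean-imputes missing dosages per locus, centers columns, and takes
scores and eigenvalue shares from the covariance eigendecomposition (full
SVD). Variance proportions are λᵢ/Σλ; a zero-variance matrix is an error
rather than a degenerate result. One phrasing in the source material
attributes the tree to maximum likelihood and another to UPGMA; the
Methods-level statement (UPGMA) is implemented.

## Synthetic study conditions

The default fixture is a 100-kb uniform-composition genome with 200
samples — large enough that every failure mode has a dedicated planted
site and small enough that the full pipeline runs in seconds. Background
sequence is scrubbed of accidental threshold-level SSRs (detected runs
are broken by a single substitution, iterated to a fixed point) so that
planted SSR truth is exact; planted arrays get periodicity-breaking
boundary bases so each scan reports exactly the planted (start, motif,
count). Planted features: SSR arrays of every motif length at and above
threshold; InDels covering every size class, type, and Perfect-filter
failure mode (11/20/49 bp lengths, MAF 0.04, duplicated flanks — one pair
as reverse complements — and multi-allelic sites); threshold-edge plants
at MAF 0.05, MAF 0.10 and missing rate 0.50; and five Multi-InDel
clusters — {3,5,9} collision-free, {3,4,7} colliding (3+4=7), two
collision-free clusters 150 bp apart that the spacing rule must remove,
and a four-member {3,5,10,−9} cluster.

Genotypes are planted at *exact-count* frequencies: the allele count is
fixed at round(f · 2n′) over the n′ non-missing samples and dealt by
random permutation (Hardy–Weinberg conditioned on the allele count), and
missing cells are an exact-count random subset. This keeps threshold
verdicts deterministic — a site planted at MAF 0.04 can never drift over
the 0.05 boundary — while still randomizing arrangement. All randomness
flows from the single spec seed; outputs are byte-identical across runs.

The generator does not emulate: linkage disequilibrium or any population
history, sequencing error, genotype-calling error correlated with allele
length, GC bias (a knob exists but is off), imperfect/compound SSRs, or
reference bias. Passing tests therefore demonstrate correctness of the
classification, filtering, enumeration and clustering logic under clean
conditions — not robustness to real-data artifacts such as alignment
slippage around long repeat arrays.

The germplasm panel generator plants k clusters as disjoint blocks of
cluster-private homozygous loci plus shared segregating loci (frequency
0.3) and 2% missingness; separation is deterministic, so tree-cut and
PCA recovery checks are exact rather than probabilistic.

## Numerical and formatting choices

Newick branch lengths are written with 12 significant digits so trees
round-trip through external parsers within 1e-9; sample identifiers avoid
underscores, which bare newick labels turn into spaces on re-parse.
Tables are written as TSV with fixed column order and stable sorts
(chromosome, position) so repeated runs are byte-identical. The Browse
export mirrors the same rows as TSV and JSON-lines. Thresholds are all
configurable via flags or a flat YAML config (flags win) and the
effective configuration and per-stage input/output counts are logged, so
the candidate → grouped → distinct → spaced funnel can be reconstructed
from logs alone.

## Known limitations

- Flank uniqueness by exact matching will call "unique" a flank whose
  near-identical (1-mismatch) copy exists elsewhere unless the optional
  neighborhood mode is enabled; an alignment-based screen would be more
  permissive, not less.
- Left-alignment of multi-allelic records normalizes all alleles jointly;
  records mixing an indel with an equal-length substitution keep the
  substitution allele as a zero-change allele.
- The sliding-window grouping is greedy; it does not search over
  alternative partitions of dense candidate runs for a globally maximal
  panel.
- UPGMA is O(n³) in samples and the distance matrix O(n²); the germplasm
  module targets panels of hundreds, not tens of thousands, of lines.
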