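# omniindel

A toolkit for genome-wide insertion/deletion (InDel) marker development and
downstream germplasm analysis, aimed at crop genetics and molecular-breeding
labs that mine variant calls for assay-ready markers.

InDels are the second most abundant variant class in plant genomes and,
unlike SNPs, can be genotyped by simple size separation (PAGE, fluorescent
capillary electrophoresis) as well as by chip and KASP platforms.
`omniindel` takes a reference genome (FASTA), per-sample variant calls
(VCF v4.2) and optionally whole-genome-alignment variant tables (SyRI-style
TSV), and produces:

- **Size/type classification** of every length-changing site into
  small (SOI, 1–2 bp), medium (MOI, 3–49 bp), large (LOI, 50–999 bp) and
  huge (HOI, ≥ 1000 bp) classes, and into insertion / deletion / mixed
  types (a *mixed* site carries both an insertion and a deletion allele).
- **SSR-InDel detection**: a MISA-style scan for perfect tandem repeats of
  1–6 bp motifs (minimum copies 10/6/5/4/3/3 by motif length) and a
  two-tier classification of InDels that overlap an SSR, flagging those
  whose inserted/deleted sequence is a whole number of motif copies.
- **Perfect InDel filtering**: marker-grade sites that are dimorphic,
  3–10 bp, have minor allele frequency (MAF) ≥ 0.05 and at least one
  30-bp flank occurring exactly once in the genome (exact matching over
  both strands).
- **Multi-InDel panel design**: clusters of k ≥ 3 dimorphic medium InDels
  within a 200-bp amplicon whose 2^k theoretical haplotypes all have
  pairwise-distinct lengths — the *distinct subset-sum* condition on the
  member length deltas, so a single fragment-size read identifies the
  haplotype. Adjacent clusters closer than 200 bp are removed.
- **Germplasm analysis**: allele-sharing genetic distance over dosage
  matrices, UPGMA trees (average linkage, ultrametric, newick export) and
  PCA with per-component variance proportions.
- **Synthetic fixtures**: a seeded generator that plants SSR arrays,
  InDels of every class and type at exact allele frequencies, duplicated
  flanks, and Multi-InDel clusters with declared subset-sum behaviour —
  with a machine-readable truth table, so the whole pipeline is testable
  without any external data.

## The core conditions

A site enters the Perfect InDel set when, in order: 3 ≤ |Δℓ| ≤ 10 bp;
exactly two observed alleles; at least one 30-bp flank is single-copy in
the genome; MAF ≥ 0.05. The verdict records the first failing criterion.

A Multi-InDel with member deltas Δ₁…Δₖ is accepted when every subset sum
Σ_{i∈S} Δᵢ over the 2^k subsets S is unique, each member is a dimorphic
3–10 bp InDel with MAF > 0.1 and missing rate < 0.5, k ≥ 3, the reference
span is ≤ 200 bp, and the gap to the nearest neighbouring cluster exceeds
200 bp. The expected amplicon length of haplotype S is the reference span
plus Σ_{i∈S} Δᵢ.

## Worked example

Generate the default synthetic study (100-kb genome, 200 samples, planted
SSRs, InDels and clusters) and design the Multi-InDel panel:

```sh
omniindel simulate --seed 17 --out fix/
omniindel multi --vcf fix/variants.vcf --genome fix/genome.fa --out out/
```

`out/multi_panel.tsv` then contains:

```
chrom  span_start  span_end  span_length  k        member_positions length_deltas
 chr1       40001     40120          119  3       40001,40061,40120         3,5,9
 chr1       47001     47159          158  4 47001,47051,47101,47150     3,5,10,-9
```

Exactly the two planted collision-free, well-spaced clusters survive: the
planted {3,4,7} cluster is rejected because 3 + 4 = 7 makes two haplotypes
the same length, and a planted pair of clusters 150 bp apart is removed by
the spacing rule. The first rows of `out/multi_haplotypes.tsv` enumerate
the 2³ = 8 theoretical haplotypes of the first marker with their expected
amplicon lengths (119 bp reference span plus the selected deltas):

```
  multi_id  presence  length_offset  amplicon_length
chr1_40001       000              0              119
chr1_40001       100              3              122
chr1_40001       010              5              124
chr1_40001       110              8              127
chr1_40001       001              9              128
...
```

Running `omniindel perfect --vcf fix/variants.vcf --genome fix/genome.fa
--out perfect.tsv` on the same fixture yields verdict counts
`pass 44, length 6, dimorphic 2, flank 2, maf 1` — matching the planted
design exactly (the two `flank` failures are the sites whose flanks were
deliberately duplicated, one of them as a reverse complement).

## Layout

- `src/omniindel/variants.py` — data model, VCF/SyRI ingestion, left-align
  normalization, size/type classification, per-site allele statistics
- `src/omniindel/ssr.py` — SSR scanning and SSR/InDel dual classification
- `src/omniindel/perfect.py` — flank extraction, genome-wide copy counting,
  the Perfect filter chain, missingness reports
- `src/omniindel/multiindel.py` — candidate filter, window grouping,
  haplotype enumeration, subset-sum distinctness, spacing filter
- `src/omniindel/germplasm.py` — distance, UPGMA, newick, PCA
- `src/omniindel/fixtures.py` — synthetic data generator with truth tables
- `src/omniindel/cli.py` — subcommands, pipeline orchestration, Browse export
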