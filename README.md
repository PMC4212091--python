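# mapbias

Allelic mapping bias in RNA-seq, and what it does to eQTL discovery.

Reads that carry the non-reference allele of a variant can have a lower
probability of aligning correctly to the reference genome than reads
carrying the reference allele. Quantifications built from such
alignments are distorted in a genotype-dependent way, which can
manufacture spurious cis-eQTLs: the variant causing the mapping
artifact (or anything linked to it) shows up as a significant
association with its own gene's "expression".

`mapbias` implements the simulation-and-filtering strategy for
detecting and removing this artifact, end to end:

1. **Exhaustive read simulation.** For every variant in a phased panel,
   every potential read window overlapping the variant is generated
   once per *observed* local haplotype — the distinct allele
   combinations, over the variants inside the window, seen on at least
   one panel chromosome (all combinations in equal proportions,
   regardless of frequency). Genome-based single-end, spliced
   transcript-based, and paired-end modes are supported.
2. **Exhaustive mapping.** A deterministic built-in mapper finds *all*
   end-to-end alignments within edit distance k (default 3 for 50 bp
   reads), counting ties exactly; an adapter runs an external aligner
   (e.g. BWA) instead. A read is *correct* only if it maps uniquely to
   exactly its origin.
3. **Bias catalog.** A start site is *biased* when reads from
   different local haplotypes at that site do not map equally. A
   variant is *flagged* when its pooled reference- vs alternate-read
   mapping rates differ by more than 5% (`delta = rate_ref − rate_alt`);
   `direction=REF` is the only possibility for variants with no
   flanking variants in range, while linkage to a disruptive flanking
   variant can flip it to `ALT` (the secondary effect).
4. **Filtering.** Every RNA-seq read whose leftmost aligned position is
   a biased start site is removed — from every individual, regardless
   of genotype, so the filter cannot itself introduce genotype
   dependence.
5. **eQTL comparison.** Exon-level quantifications (leftmost-base
   assignment, >90% presence filter, total-count normalization) feed a
   cis-eQTL scan by Spearman rank correlation with gene-level
   permutation P values and Benjamini–Hochberg FDR at 10%; the
   filtered data are rescanned under the *identical* significance
   threshold and genes are classified `COMMON` / `LOST` / `GAINED`.
   Enrichment tests (Fisher exact on exon–variant overlap,
   TSS-distance-matched bias comparison) ask whether eQTL signals
   track the simulated bias.

A first-class synthetic-data module generates genomes with segmental
duplications, phased SNP/indel panels, planted provably-biased loci
(a variant's alt-allele flanking window duplicated elsewhere), and
RNA-seq cohorts with negative-binomial counts, planted true eQTLs and
planted bias-only false eQTLs, with a machine-readable truth table —
so every claim above is testable against ground truth.

## Worked example

```bash
python examples/03_cohort_eqtl_filtering.py
```

simulates a 60-individual cohort over 35 genes (20 planted true eQTLs,
5 planted bias-only false eQTLs, 10 nulls), builds the bias catalog,
filters, and rescans. Typical output:

```
biased start sites from simulation : 305
mean reads removed per individual  : 100
eQTL genes before filtering        : 28
eQTL genes after filtering         : 22
classes: {'COMMON': 22, 'NEVER': 7, 'LOST': 6, 'GAINED': 0}

lost genes (significant only before filtering):
            effect_class  p_before  p_after     dlogp  large_drop
gene002  BIAS_FALSE_EQTL  1.61e-06 3.24e-01 -5.30e+00        True
gene007  BIAS_FALSE_EQTL  2.52e-11 4.53e-02 -9.26e+00        True
gene014  BIAS_FALSE_EQTL  1.78e-05 6.39e-02 -3.56e+00        True
gene019             NULL  7.24e-03 8.31e-03 -6.01e-02       False
gene030  BIAS_FALSE_EQTL  8.13e-15 1.90e-02 -1.24e+01        True
gene031  BIAS_FALSE_EQTL  6.05e-11 1.17e-02 -8.29e+00        True
```

All five planted false eQTLs are significant before filtering and lost
after it, each with a nominal P that worsens by 3–12 orders of
magnitude (`large_drop`); all 20 true eQTL genes stay significant
(`COMMON`). The one additional lost gene is a borderline null whose P
barely moved — exactly the signature separating bias artifacts from
ordinary threshold noise.

`examples/01_bias_catalog.py` builds a variant-level catalog on a
mixed SNP/indel panel (indels flag far more often than SNPs, and a
planted duplication gives `rate_ref=1, rate_alt=0, direction=REF`);
`examples/02_paired_end_rescue.py` shows paired-end mapping flagging a
subset of the single-end flags with lower mean bias, because a
uniquely mapping mate rescues its multi-mapping partner.

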