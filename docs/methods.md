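# Methods

## The model of allelic mapping bias

A read of length L (default 50 bp) drawn from a haplotype carrying the
non-reference allele of a variant differs from the reference genome at
that allele. End-to-end alignment may then place it elsewhere (an
exact or closer match at a homologous locus), split its best score
across several loci, or fail outright — while the reference-allele
read, an exact substring of the reference, maps cleanly. Because the
artifact is genotype-dependent, it propagates into expression
quantifications and can create false cis-eQTL associations.

The detection strategy is simulation, not inference: enumerate *every
potential read* overlapping *every panel variant*, in *every observed
local haplotype combination*, map the reads back, and record where
reads carrying different alleles did not map equally. Haplotype
combinations are used in equal proportions regardless of their
population frequency, which makes the catalog deliberately
conservative: a rare haplotype that mismaps flags the site even if
almost nobody carries it. Sequencing errors are not simulated; the
catalog captures bias attributable to genetic variation alone.

### Read enumeration

For a variant with reference footprint `[pos, pos+len(ref)-1]`, window
starts are every s with `[s, s+L-1]` intersecting the footprint and
fully inside the contig. Windows are anchored in haplotype
coordinates: the read is the L bases of the haplotype-substituted
sequence starting at the projection of s, and its recorded origin is
the reference coordinate of its first aligned base under a
left-normalized projection (inserted bases project to the indel's
anchor, deleted bases to the next retained base). Reads identical in
(origin, window signature) that arise through different redundant
haplotype rows are emitted once; reads identical in sequence but from
different focal variants are kept per-variant for bookkeeping and
mapped once. Only forward-strand reads are simulated: end-to-end
alignment is symmetric under reverse complement, so the reverse strand
adds no information.

Transcript-frame enumeration applies the same machinery to the spliced
exon sequence, for variants fully inside exons; junction-spanning
reads are mapped against a joint genome+transcriptome index and their
hits collapsed by projected genomic position, so an exon-internal read
matching both the genome and the transcript counts as one location.
Paired-end fragments place mate 2's window `inner_insert` bases
(default 60, so 160 bp fragments) after mate 1's end *on the same
haplotype*; haplotype combinations are enumerated jointly per fragment.

### Mapping and the correctness policy

The built-in mapper reports, for each read, every end-to-end alignment
with unit-cost edit distance ≤ k (default 3, roughly the missing-data
tolerance of BWA-era aligners for 50 bp reads). Candidates come from a
pigeonhole seed scheme — the read is split into k+1 segments, one of
which must be edit-free in any alignment within budget — and each
candidate start is scored with a prefix-anchored edit-distance
computation (edlib SHW). Ties are enumerated exhaustively, never
sampled. The test suite proves the hit sets equal a full sliding
banded-DP scan of the genome.

A read is *correct* iff it is mapped, has a single best hit with
positive mapping quality, and its reported leftmost position equals
its recorded origin; unmapped, mismapped and multi-mapped are all
incorrect (each makes allele classes map unequally). An optional
position tolerance absorbs aligner left-shift ambiguity around indels.
For pairs, the best *pairing* (same contig, proper span within a
tolerance of 2k, minimal summed distance) must be unique and place
both mates at their origins — which is how a uniquely mapping mate
rescues a multi-mapping partner and why paired-end catalogs are
smaller than single-end ones.

One scoring caveat, deliberate and documented: under unit-cost edit
distance a SNP sitting in or beside a homopolymer run is locally
ambiguous — excising the alternate base from a read (one gap) leaves a
sequence that matches the reference one base over, tying the
substitution alignment, and the tie spans as many start sites as the
run is long. Gap-open penalties in production aligners suppress these
ties; unit costs do not. The synthetic generators therefore place
SNPs at run-free sites with alternate alleles differing from both
neighboring bases (the operational meaning of "unique flanks");
residual higher-order ties touch at most a couple of a SNP's ~50
start sites (|delta| ≤ 0.04, below the 5% flagging threshold).
User-supplied variants in repetitive contexts will show such ties at
the site level, which is faithful to what a unit-cost mapper does.

### Bias catalog

Per (variant, start): biased iff the reads' correctness values are not
all equal across local haplotypes. Per variant, pooled over all
windows: `rate_ref`, `rate_alt`, `delta = rate_ref − rate_alt`,
flagged iff |delta| > 0.05 (strict), direction REF/ALT by the sign of
delta, and `ref_ratio = n_ref_correct / (n_ref_correct +
n_alt_correct)` for cross-catalog rank correlations. For a variant
with no flanking variants in any window, ALT-favoring bias is
provably impossible: if the reference read multimaps, an exact copy of
its window exists, and the alternate read then ties at that copy too;
if the reference read maps uniquely, it is correct. The ALT direction
arises only through linkage — a flanking variant whose alternate
allele mismaps drags down reads that carry the *reference* allele of
its neighbor (`make_linked_flank_panel` constructs the canonical
case: two SNPs in perfect negative LD, the second one's alt window
duplicated).

Planting a *reference*-allele window copy does not mirror this: it
makes reference reads exact two-location multi-mappers and alternate
reads tie at distance 1 against both locations, so both allele classes
fail and delta is ~0. The `allele="ref"` option exists and does
exactly that.

### Filtering, quantification, eQTL mapping

Filtering removes every read whose SAM POS is in the biased-site set,
identically for all individuals (genotype-blind by construction);
unmapped reads are retained, conservation (input = retained + removed)
is exact, and the operation is idempotent. Exon counting assigns a
read to the exon containing its leftmost base (consistent with
start-site semantics); exons with >0 reads in strictly more than 90%
of individuals are kept; columns are scaled by total exon-mapped reads
(downstream tests are rank-based, so the scale constant is
irrelevant), with optional least-squares covariate regression on log
counts.

The cis-eQTL scan tests every (exon, cis variant) pair by Spearman
rank correlation (midrank ties) between normalized expression and alt
dosage 0/1/2, with variants taken within `cis_window` of the TSS and
above the sample MAF floor. The gene statistic is the minimum nominal
P, tie-broken by (variant position, exon order). Gene-level empirical
P permutes individual labels (the same permutation order for all genes
in a run) and uses the add-one estimator `p = (1 + #{perm best ≤
observed}) / (n_perm + 1)`. Gene significance is Benjamini–Hochberg on
empirical P at FDR 10%; the realized empirical-P threshold is recorded
and reused verbatim for the filtered rescan, so before/after
differences cannot come from threshold drift. Genes are then COMMON /
LOST / GAINED / NEVER; `dlogp = log10 p_before − log10 p_after` on the
gene-best nominal P, with `large_drop` marking lost genes beyond a
drop threshold. Enrichment tests use scipy's Fisher exact
(cross-checked in tests against exact hypergeometric enumeration) and
Mann–Whitney on |delta|, with the TSS-matched null sampled from 10
equal-occupancy distance bins (without replacement when possible).

## The synthetic-data generator

What it emulates: a reference genome (uniform ACGT, no Ns) with
optional segmental duplications; a phased panel of SNPs and indels
(≤6 bp) with MAF uniform on [0.01, 0.5] and independent per-chromosome
Bernoulli alleles, forced to segregate; multi-exon gene models; and an
RNA-seq cohort whose per-gene fragment counts are negative binomial
(dispersion 0.1, variance μ + 0.1μ²) with reads drawn uniformly from
exons on each individual's two haplotypes and aligned through the same
built-in mapper as the simulation.

Planted structure: `plant_biased_duplication` appends a copy of a
SNP's alt-allele flanking window (by default 2L−1 bp; a shorter
`copy_len` grades the biased fraction of the SNP's start sites), which
provably makes every covered alt read mismap while reference reads
stay unique. Cohort fixtures (`build_cohort_fixture`) lay out two-exon
genes: TRUE_EQTL genes get an upstream regulatory SNP multiplying
expression by `effect_size` (default 2) per alt allele;
BIAS_FALSE_EQTL genes get a planted-duplication SNP centered in a
110 bp first exon — 50 of its 81 read starts are biased, so
alt-homozygotes keep ~18% of first-exon reads. That geometry matters:
if *every* start were biased, alt-homozygotes would have zero counts
and the >90% presence filter would delete the exon before any eQTL
scan, so no false association would ever be planted; with most starts
biased, the artifact is a strong, clearly spurious association that
filtering then removes.

What it does not emulate: linkage disequilibrium (except the explicit
linked-flank fixture), realistic allele-frequency spectra, sequencing
errors, base-quality variation, splice-isoform diversity, strand
effects, >2 alleles per site. Passing tests therefore demonstrate the
*logic* of the method — enumeration, exhaustive mapping, catalog
semantics, filter behavior, statistical calibration — on data whose
ground truth is known, not performance on human-scale data.

## Numerical and scale choices

- Built-in mapper: k=3, seed length 12, mapq 37 unique / 0 tied;
  pair-span tolerance 2k. Deterministic throughout; all randomness
  flows from explicit numpy Generators seeded per run.
- Desk-scale study conditions: cohorts of 60 individuals, 35 genes
  (20/5/10 true/bias/null), NB mean 100 fragments per gene, 300
  permutations; null-calibration runs use 100 individuals and 200
  permutations. The fixture genome is ~41 kb, so the cis window is
  2,500 bp — the role a 1 Mb window plays on a 3 Gb genome (the
  package default remains 1 Mb).
- "Clear false positive" drop threshold: 3 log10 units at fixture
  depth (attainable −log10 P here is ~8–16, where deep real studies
  use a threshold of 20); a gene untested after filtering takes
  p_after = 1, and nominal P is floored at 1e-300 before logs.
- Empirical P values live on the grid i/(n_perm+1); calibration tests
  compare against that exact discrete null rather than a continuous
  uniform.

## Known limitations

- Unit-cost edit distance (no affine gaps) — see the scoring caveat
  above; site-level catalogs near indels and SNP-adjacent-repeat edges
  differ slightly from gap-penalized aligners.
- The built-in mapper is exhaustive but desk-scale (in-memory index,
  pure Python orchestration); genome-scale runs should use the
  external-aligner adapter.
- The transcript mode assumes one transcript per gene (caller-supplied
  choice) and variants fully inside exons.
- Filtering matches read start sites exactly; cohorts whose read
  length differs from the simulated length are not adjusted.
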