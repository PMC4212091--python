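"""Synthetic genomes, variant panels, annotations and RNA-seq cohorts.

Everything downstream of this module treats its outputs exactly as it
would treat real data: a reference genome (FASTA), a phased variant
panel (VCF), transcript models (GTF) and per-individual alignments
(BAM).  The generator's job is to produce data with the statistical
structure the analysis assumes, including

* segmental duplications, so that some loci genuinely multi-map;
* planted single-variant duplications, so that specific SNPs provably
  exhibit allelic mapping bias (the non-reference read has a second,
  equally good or better, genomic match);
* planted true eQTLs (genotype-dependent expression) and planted
  bias-only false eQTLs (equal true expression, but reads from the
  alternate haplotype mismap), with a machine-readable truth table.

Coordinates are 1-based inclusive throughout (VCF/GTF convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Global knobs of the read simulation.

    read_len: simulated read length in bases.
    inner_insert: unsequenced gap between paired-end mates, in bases
        (so the fragment spans 2*read_len + inner_insert bases).
    maf_min: minor-allele-frequency floor of the variant panel.
    """

    read_len: int = 50
    inner_insert: int = 60
    maf_min: float = 0.01
    rng_seed: int = 0
    genome_len: int = 100_000
    n_individuals: int = 100

    def __post_init__(self) -> None:
        if self.read_len < 20:
            raise ValueError("read_len must be >= 20")
        if self.inner_insert < 0:
            raise ValueError("inner_insert must be >= 0")
        if not (0.0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")


@dataclass(frozen=True)
class VariantRecord:
    """One SNP or indel, VCF-style: pos is the 1-based anchor position.

    For indels ``ref_seq`` and ``alt_seq`` share their first (anchor)
    base; a SNP has single-base ref and alt.
    """

    vid: str
    contig: str
    pos: int
    ref_seq: str
    alt_seq: str
    maf: float

    def __post_init__(self) -> None:
        if not self.ref_seq:
            raise ValueError("ref_seq must be non-empty")

    @property
    def vclass(self) -> str:
        return "SNP" if len(self.ref_seq) == 1 and len(self.alt_seq) == 1 else "INDEL"

    @property
    def end(self) -> int:
        """Last reference base of the variant footprint (1-based)."""
        return self.pos + len(self.ref_seq) - 1


@dataclass
class HaplotypePanel:
    """Phased haplotypes over an ordered variant list.

    ``haplotypes`` is a (2 * n_individuals) x n_variants int8 matrix of
    0 (reference) / 1 (alternate); haplotypes 2i and 2i+1 belong to
    sample i.
    """

    variants: list[VariantRecord]
    haplotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.sample_ids), len(self.variants)):
            raise ValueError("haplotype matrix shape mismatch")
        self._index = {v.vid: i for i, v in enumerate(self.variants)}

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def variant(self, vid: str) -> VariantRecord:
        return self.variants[self._index[vid]]

    def column(self, vid: str) -> np.ndarray:
        return self.haplotypes[:, self._index[vid]]

    def dosages(self) -> pd.DataFrame:
        """Variants x individuals matrix of alt-allele dosages (0/1/2)."""
        d = self.haplotypes.reshape(self.n_individuals, 2, len(self.variants)).sum(axis=1)
        return pd.DataFrame(
            d.T, index=[v.vid for v in self.variants], columns=self.sample_ids
        )

    def individual_haplotypes(self, sample: int) -> tuple[np.ndarray, np.ndarray]:
        return self.haplotypes[2 * sample], self.haplotypes[2 * sample + 1]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sorted, non-overlapping exons on one contig."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ex = list(self.exons)
        if any(e[0] > e[1] for e in ex):
            raise ValueError("exon start > end")
        if any(ex[i][1] >= ex[i + 1][0] for i in range(len(ex) - 1)):
            raise ValueError("exons must be sorted and non-overlapping")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in ex))

    @property
    def tss(self) -> int:
        """5'-most position respecting strand."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class TruthTable:
    """Planted ground truth for the cohort simulation.

    ``genes``: one row per gene with columns gene_id, effect_class
    (TRUE_EQTL | BIAS_FALSE_EQTL | NULL), eqtl_variant (id or ''),
    effect_size (per-alt-allele expression fold change), base_mean.
    ``variants``: one row per variant with column planted_bias (bool).
    """

    genes: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        bad = self.genes.query("effect_class == 'BIAS_FALSE_EQTL' and effect_size != 1")
        if len(bad):
            raise ValueError("BIAS_FALSE_EQTL genes must have effect_size == 1")

    def to_tsv(self, gene_path: str | Path, variant_path: str | Path) -> None:
        self.genes.to_csv(gene_path, sep="\t", index=False)
        self.variants.to_csv(variant_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, gene_path: str | Path, variant_path: str | Path) -> "TruthTable":
        return cls(
            genes=pd.read_csv(gene_path, sep="\t", keep_default_na=False),
            variants=pd.read_csv(variant_path, sep="\t"),
        )


# ---------------------------------------------------------------------------
# reference + panel generation
# ---------------------------------------------------------------------------

def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _to_str(arr: np.ndarray) -> str:
    return "".join(ALPHABET[b] for b in arr)


def _segregating(rng: np.random.Generator, haps: np.ndarray) -> np.ndarray:
    """Force every column to carry both alleles (panel invariant)."""
    n = haps.shape[0]
    for j in np.flatnonzero(haps.sum(axis=0) == 0):
        haps[rng.integers(n), j] = 1
    for j in np.flatnonzero(haps.sum(axis=0) == n):
        haps[rng.integers(n), j] = 0
    return haps



def _clean_snp_site(seq: str, pos: int) -> bool:
    """True when the reference base at pos is not part of a homopolymer.

    If it is (either neighbor equals it), excising the alternate base
    from a read re-aligns the read one base over at the same unit cost,
    a local flank ambiguity rather than unique sequence.
    """
    b = seq[pos - 1]
    left = seq[pos - 2] if pos >= 2 else ""
    right = seq[pos] if pos < len(seq) else ""
    return b != left and b != right


def _snp_alt(rng: np.random.Generator, seq: str, pos: int) -> str:
    """Alt base differing from the ref base and both neighbors.

    A SNP whose alternate allele equals an adjacent reference base has
    a gap-shifted unit-cost alignment tied with the substitution, a
    local flank ambiguity; panels model variants in unique sequence,
    so such alleles are not drawn.
    """
    banned = {seq[pos - 1]}
    if pos >= 2:
        banned.add(seq[pos - 2])
    if pos < len(seq):
        banned.add(seq[pos])
    choices = [b for b in ALPHABET if b not in banned]
    return choices[int(rng.integers(0, len(choices)))]


def make_reference_panel(
    config: SimulationConfig,
    n_snps: int,
    n_indels: int = 0,
    dup_spec: list[tuple[int, int]] | None = None,
    contig: str = "chr1",
    max_indel: int = 6,
    min_spacing: int | None = None,
) -> tuple[dict[str, str], HaplotypePanel]:
    """Generate a random genome plus a phased variant panel.

    dup_spec is a list of (length, count) segmental duplications: for
    each entry a donor segment is copied ``count`` extra times into the
    genome (overwriting random non-overlapping acceptor regions), so
    reads from those regions genuinely multi-map.

    Variant positions are uniform over the genome away from the ends
    (margin of read_len + max_indel) and mutually separated so variant
    footprints never overlap.  MAFs are uniform on [maf_min, 0.5] and
    haplotype alleles are independent Bernoulli draws per chromosome,
    forced to segregate.  Deterministic given config.rng_seed.
    """
    dup_spec = dup_spec or []
    if n_snps + n_indels < 1:
        raise ValueError("at least one variant required")
    for length, _count in dup_spec:
        if length >= config.genome_len / 2:
            raise ValueError("duplication length must be < genome_len / 2")
        if config.genome_len < 10 * length:
            raise ValueError("genome_len must be >= 10x the longest duplication")

    rng = np.random.default_rng(config.rng_seed)
    genome = _random_genome(rng, config.genome_len)

    # paste segmental duplications: donor stays, copies overwrite
    used: list[tuple[int, int]] = []
    for length, count in dup_spec:
        donor = int(rng.integers(0, config.genome_len - length))
        used.append((donor, donor + length))
        segment = genome[donor : donor + length].copy()
        placed = 0
        while placed < count:
            a = int(rng.integers(0, config.genome_len - length))
            if any(a < e and a + length > s for s, e in used):
                continue
            genome[a : a + length] = segment
            used.append((a, a + length))
            placed += 1

    margin = config.read_len + max_indel + 10
    spacing = max_indel * 2 + 2 if min_spacing is None else min_spacing
    jitter = max_indel + 2
    grid = spacing + jitter
    n_var = n_snps + n_indels
    lo, hi = margin, config.genome_len - margin
    n_slots = (hi - lo) // grid
    if n_slots < n_var:
        raise ValueError("genome too small for requested variant count")
    # uniform grid slots plus jitter: consecutive positions are >= spacing apart
    slots = np.sort(rng.choice(n_slots, size=n_var, replace=False))

    is_indel = np.zeros(n_var, dtype=bool)
    if n_indels:
        is_indel[rng.choice(n_var, size=n_indels, replace=False)] = True

    seq = _to_str(genome)
    positions = np.empty(n_var, dtype=np.int64)
    for i in range(n_var):
        base = lo + int(slots[i]) * grid
        offsets = rng.permutation(jitter)
        pick = base + int(offsets[0])
        if not is_indel[i]:
            for off in offsets:  # prefer a run-free site for SNPs
                if _clean_snp_site(seq, base + int(off) + 1):
                    pick = base + int(off)
                    break
        positions[i] = pick
    variants: list[VariantRecord] = []
    mafs = rng.uniform(config.maf_min, 0.5, size=n_var)
    for i, pos0 in enumerate(positions):
        pos = int(pos0) + 1  # 1-based
        refbase = seq[pos - 1]
        if not is_indel[i]:
            ref_seq, alt_seq = refbase, _snp_alt(rng, seq, pos)
        else:
            ln = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:  # insertion
                ins = _to_str(rng.integers(0, 4, size=ln, dtype=np.int8))
                ref_seq, alt_seq = refbase, refbase + ins
            else:  # deletion
                ref_seq, alt_seq = seq[pos - 1 : pos - 1 + ln + 1], refbase
        vid = f"v{i:04d}"
        variants.append(VariantRecord(vid, contig, pos, ref_seq, alt_seq, float(mafs[i])))

    haps = (rng.random((2 * config.n_individuals, n_var)) < mafs).astype(np.int8)
    haps = _segregating(rng, haps)
    panel = HaplotypePanel(
        variants=variants,
        haplotypes=haps,
        sample_ids=[f"IND{i:03d}" for i in range(config.n_individuals)],
    )
    return {contig: seq}, panel


def plant_biased_duplication(
    reference: dict[str, str],
    panel: HaplotypePanel,
    variant_id: str,
    config: SimulationConfig,
    allele: str = "alt",
    genes: list[TranscriptModel] | None = None,
    insert_pos: int | None = None,
    copy_len: int | None = None,
) -> tuple[dict[str, str], tuple[str, int, int]]:
    """Insert a copy of a SNP's flanking window carrying ``allele``.

    By default the copy spans read_len - 1 bases either side of the
    SNP, so every read over the SNP on the copied haplotype has a
    second genomic match at least as good as its origin; a shorter
    ``copy_len`` (>= read_len, centered on the SNP) captures only the
    reads fully contained in it, grading the biased fraction of the
    SNP's start sites from one window up to all of them:

    * allele='alt': alternate-allele reads find an exact match at the
      copy (better than the 1-mismatch match at the origin) and mismap,
      while reference reads stay unique at the origin — the classic
      reference-favoring bias.
    * allele='ref': reference reads become exact two-location
      multi-mappers, and alternate reads tie between origin and copy;
      reads on both haplotypes then fail to map uniquely.

    By default the copy is appended to the end of the contig (no
    coordinate shift for any existing feature); passing ``insert_pos``
    overwrites the genome at that position instead, which is rejected
    if it would disturb a gene or a variant's read neighbourhood.

    Returns the modified reference and the copy's (contig, start, end).
    """
    v = panel.variant(variant_id)
    if v.vclass != "SNP":
        raise ValueError("biased duplications are planted at SNPs")
    seq = reference[v.contig]
    L = config.read_len
    if copy_len is None:
        copy_len = 2 * L - 1
    if copy_len < L:
        raise ValueError("copy_len must be >= read_len")
    h1 = (copy_len - 1) // 2
    a, b = v.pos - h1, v.pos + (copy_len - 1 - h1)  # 1-based inclusive window
    if a < 1 or b > len(seq):
        raise ValueError("variant too close to contig end to plant a duplication")
    window = seq[a - 1 : v.pos - 1] + (v.alt_seq if allele == "alt" else v.ref_seq) + seq[v.pos : b]

    out = dict(reference)
    if insert_pos is None:
        pad = "".join(
            ALPHABET[i % 4] for i in range(10)
        )  # deterministic spacer so the copy does not abut real sequence
        start = len(seq) + len(pad) + 1
        out[v.contig] = seq + pad + window
        loc = (v.contig, start, start + len(window) - 1)
    else:
        end = insert_pos + len(window) - 1
        if end > len(seq):
            raise ValueError("insertion window extends past contig end")
        for t in genes or []:
            s0, e0 = t.span
            if insert_pos <= e0 and end >= s0:
                raise ValueError(f"insertion overlaps gene {t.gene_id}")
        for w in panel.variants:
            if insert_pos <= w.end + L and end >= w.pos - L:
                raise ValueError(f"insertion overlaps read neighbourhood of {w.vid}")
        out[v.contig] = seq[: insert_pos - 1] + window + seq[end:]
        loc = (v.contig, insert_pos, end)
    return out, loc


def make_linked_flank_panel(
    config: SimulationConfig,
    gap: int = 5,
    n_background: int = 10,
) -> tuple[dict[str, str], HaplotypePanel, str, str]:
    """Fixture for the secondary (alt-favoring) bias effect.

    Two SNPs A and B sit ``gap`` bases apart in perfect negative LD:
    observed haplotypes are (A=ref, B=alt) and (A=alt, B=ref).  A
    duplication of B's alt-allele window is planted, so reads carrying
    B's alternate allele mismap.  Since those reads carry A's
    *reference* allele, A ends up biased in favor of its alternate
    allele — bias direction ALT purely through linkage.

    Returns (reference, panel, vid_A, vid_B).
    """
    rng = np.random.default_rng(config.rng_seed)
    genome = _random_genome(rng, config.genome_len)
    seq = _to_str(genome)
    pos_a = config.genome_len // 2
    pos_b = pos_a + gap
    margin = config.read_len + 16

    def _snp(vid: str, pos: int, maf: float) -> VariantRecord:
        return VariantRecord(vid, "chr1", pos, seq[pos - 1], _snp_alt(rng, seq, pos), maf)

    variants = [_snp("vA", pos_a, 0.3), _snp("vB", pos_b, 0.3)]
    taken = {pos_a, pos_b}
    i = 0
    while len(variants) < 2 + n_background:
        pos = int(rng.integers(margin, config.genome_len - margin))
        if any(abs(pos - q) < 2 * config.read_len for q in taken):
            continue
        variants.append(_snp(f"bg{i:03d}", pos, float(rng.uniform(config.maf_min, 0.5))))
        taken.add(pos)
        i += 1
    order = np.argsort([v.pos for v in variants])
    variants = [variants[j] for j in order]
    idx = {v.vid: j for j, v in enumerate(variants)}

    n_hap = 2 * config.n_individuals
    haps = (rng.random((n_hap, len(variants))) < [v.maf for v in variants]).astype(np.int8)
    # perfect negative LD between A and B
    carrier = rng.random(n_hap) < 0.5
    haps[:, idx["vA"]] = np.where(carrier, 1, 0)
    haps[:, idx["vB"]] = np.where(carrier, 0, 1)
    haps = _segregating(rng, haps)
    panel = HaplotypePanel(variants, haps, [f"IND{i:03d}" for i in range(config.n_individuals)])
    reference, _ = plant_biased_duplication({"chr1": seq}, panel, "vB", config, allele="alt")
    return reference, panel, "vA", "vB"


# ---------------------------------------------------------------------------
# cohort fixture: genes + planted eQTLs
# ---------------------------------------------------------------------------

@dataclass
class CohortFixture:
    """A complete synthetic study: genome, panel, annotation, truth."""

    config: SimulationConfig
    reference: dict[str, str]
    panel: HaplotypePanel
    transcripts: list[TranscriptModel]
    truth: TruthTable


def build_cohort_fixture(
    config: SimulationConfig,
    n_true: int = 20,
    n_bias: int = 5,
    n_null: int = 10,
    base_mean: float = 100.0,
    effect_size: float = 2.0,
    eqtl_maf: tuple[float, float] = (0.2, 0.5),
    bias_exon_len: int = 110,
    clean_exon_len: int = 200,
    contig: str = "chr1",
) -> CohortFixture:
    """Lay out a genome of two-exon genes with planted eQTLs.

    Each gene has two exons.  TRUE_EQTL genes get a cis SNP upstream of
    the gene (outside exons) whose alternate allele multiplies the
    gene's expected expression by ``effect_size``.  BIAS_FALSE_EQTL
    genes have no expression effect (effect_size 1) but carry a SNP in
    the middle of a short first exon whose alt-allele flanking window
    is duplicated elsewhere, so alt-haplotype reads over it mismap.
    The exon is sized so the SNP's read windows cover most but not all
    of its start positions: alt-homozygous individuals keep enough
    first-exon expression to survive presence filtering, which is what
    lets the mapping artifact masquerade as a real eQTL.
    NULL genes have neither.  Every gene also gets one neutral exonic
    SNP in its second exon (unique sequence, hence unbiased), so exons
    overlap variants the way real exons do.

    Gene spacing, exon sizes and the per-gene negative-binomial depth
    are chosen so a cohort of ``config.n_individuals`` has conventional
    desk-scale eQTL power; MAFs of planted eQTL/bias SNPs are drawn
    from ``eqtl_maf``.
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.read_len
    if bias_exon_len < L + 10:
        raise ValueError("bias_exon_len must exceed read_len by a margin")

    n_genes = n_true + n_bias + n_null
    intron = 150
    upstream = 300  # gap holding the TRUE-eQTL regulatory SNP
    gene_pitch = upstream + bias_exon_len + intron + clean_exon_len + 400
    genome_len = n_genes * gene_pitch + 4 * (L + 50)
    genome = _random_genome(rng, genome_len)
    seq_list = list(_to_str(genome))

    classes = (
        ["TRUE_EQTL"] * n_true + ["BIAS_FALSE_EQTL"] * n_bias + ["NULL"] * n_null
    )
    rng.shuffle(classes)

    transcripts: list[TranscriptModel] = []
    variants: list[VariantRecord] = []
    gene_rows = []
    cursor = L + 60

    seq_str = "".join(seq_list)

    def _snp_at(vid: str, pos: int, maf: float) -> VariantRecord:
        return VariantRecord(vid, contig, pos, seq_list[pos - 1], _snp_alt(rng, seq_str, pos), maf)

    for g, cls in enumerate(classes):
        gid = f"gene{g:03d}"
        e1_start = cursor + upstream
        e1_end = e1_start + bias_exon_len - 1
        e2_start = e1_end + 1 + intron
        e2_end = e2_start + clean_exon_len - 1
        t = TranscriptModel(gid, f"{gid}.t1", contig, "+", ((e1_start, e1_end), (e2_start, e2_end)))
        transcripts.append(t)

        def _pick(lo_, hi_):
            # prefer a run-free site so the SNP sits in unique flank
            for _ in range(20):
                p = int(rng.integers(lo_, hi_))
                if _clean_snp_site(seq_str, p):
                    return p
            return p

        eqtl_vid = ""
        planted = False
        maf = float(rng.uniform(*eqtl_maf))
        if cls == "TRUE_EQTL":
            eqtl_vid = f"{gid}_e"
            variants.append(_snp_at(eqtl_vid, _pick(cursor + 20, cursor + upstream - 20), maf))
        elif cls == "BIAS_FALSE_EQTL":
            eqtl_vid = f"{gid}_b"
            mid = e1_start + bias_exon_len // 2 - 1
            variants.append(_snp_at(eqtl_vid, _pick(mid - 4, mid + 5), maf))
            planted = True
        # neutral exonic SNP in the clean exon, away from its edges
        nv = f"{gid}_n"
        variants.append(
            _snp_at(nv, _pick(e2_start + L, e2_start + clean_exon_len - L),
                    float(rng.uniform(config.maf_min, 0.5)))
        )

        gene_rows.append(
            dict(
                gene_id=gid,
                effect_class=cls,
                eqtl_variant=eqtl_vid,
                effect_size=effect_size if cls == "TRUE_EQTL" else 1.0,
                base_mean=base_mean,
                planted_bias_variant=eqtl_vid if planted else "",
            )
        )
        cursor += gene_pitch

    variants.sort(key=lambda v: v.pos)
    mafs = np.array([v.maf for v in variants])
    haps = (rng.random((2 * config.n_individuals, len(variants))) < mafs).astype(np.int8)
    haps = _segregating(rng, haps)
    panel = HaplotypePanel(
        variants, haps, [f"IND{i:03d}" for i in range(config.n_individuals)]
    )

    reference = {contig: "".join(seq_list)}
    planted_ids = [r["planted_bias_variant"] for r in gene_rows if r["planted_bias_variant"]]
    for vid in planted_ids:
        reference, _ = plant_biased_duplication(
            reference, panel, vid, config, allele="alt", genes=transcripts
        )

    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        variants=pd.DataFrame(
            dict(
                vid=[v.vid for v in variants],
                planted_bias=[v.vid in set(planted_ids) for v in variants],
            )
        ),
    )
    return CohortFixture(config, reference, panel, transcripts, truth)


# ---------------------------------------------------------------------------
# cohort read simulation
# ---------------------------------------------------------------------------

def _exon_haplotype_seq(
    reference: dict[str, str],
    exon: tuple[int, int],
    variants: list[VariantRecord],
    alleles: np.ndarray,
    contig: str,
) -> str:
    """Exon sequence with this haplotype's SNP alleles substituted.

    Cohort exons carry SNPs only, so coordinates are unshifted.
    """
    s, e = exon
    seq = list(reference[contig][s - 1 : e])
    for v, a in zip(variants, alleles):
        if a and s <= v.pos <= e:
            seq[v.pos - s] = v.alt_seq
    return "".join(seq)


def simulate_rnaseq_cohort(
    fixture: CohortFixture,
    out_dir: str | Path,
    mapper=None,
    dispersion: float = 0.1,
    rng_seed: int | None = None,
    min_individuals: int = 10,
) -> tuple[list[Path], pd.DataFrame]:
    """Simulate and align an RNA-seq cohort; one sorted BAM per individual.

    Per gene and individual the fragment count is negative binomial
    with mean base_mean * effect_size**dosage and the given dispersion
    (var = mu + dispersion * mu^2).  Fragments are 50 bp single-end
    reads drawn uniformly from the gene's exons on one of the
    individual's two haplotypes.  Reads are aligned back to the
    reference with the built-in mapper: a unique best hit is recorded
    at the mapped position (which, for mismapping alt-haplotype reads
    over planted-bias loci, is the duplicated copy); reads with tied
    best hits or no hit within the edit budget are written unmapped.

    Returns the BAM paths and a per-individual table of true fragment
    counts per gene (before any mapping loss).
    """
    import pysam

    from .mapping import BuiltinMapper

    cfg = fixture.config
    if cfg.n_individuals < min_individuals:
        raise ValueError(f"need >= {min_individuals} individuals for eQTL use")
    rng = np.random.default_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if mapper is None:
        mapper = BuiltinMapper(fixture.reference)

    L = cfg.read_len
    contigs = sorted(fixture.reference)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(fixture.reference[c])} for c in contigs],
        }
    )
    tid = {c: i for i, c in enumerate(contigs)}

    genes = fixture.truth.genes
    tmodels = {t.gene_id: t for t in fixture.transcripts}
    dosage = fixture.panel.dosages()
    vids = [v.vid for v in fixture.panel.variants]

    # per-gene cached haplotype exon sequences and variant lists
    exon_vars: dict[str, list[list[VariantRecord]]] = {}
    for gid, t in tmodels.items():
        exon_vars[gid] = [
            [v for v in fixture.panel.variants if ex[0] <= v.pos <= ex[1]] for ex in t.exons
        ]

    vidx = {vid: j for j, vid in enumerate(vids)}
    aln_cache: dict[str, tuple] = {}
    hapseq_cache: dict[tuple, str] = {}

    def _aligned(seq: str):
        hit = aln_cache.get(seq)
        if hit is None:
            res = mapper.align(seq)
            hit = (res.contig, res.pos) if (res.mapped and res.n_best_hits == 1) else None
            aln_cache[seq] = hit if hit is not None else ()
        return hit if hit else None

    depth_rows = []
    bam_paths = []
    r = 1.0 / dispersion
    for i, sample in enumerate(fixture.panel.sample_ids):
        hapA, hapB = fixture.panel.individual_haplotypes(i)
        records = []
        n_frag_total = 0
        depth = {"individual": sample}
        for row in genes.itertuples():
            t = tmodels[row.gene_id]
            d = (
                dosage.loc[row.eqtl_variant, sample]
                if row.eqtl_variant and row.effect_class == "TRUE_EQTL"
                else 0
            )
            mu = row.base_mean * (row.effect_size ** d)
            n_frag = int(rng.negative_binomial(r, r / (r + mu)))
            depth[row.gene_id] = n_frag
            n_frag_total += n_frag
            exlens = np.array([e - s + 1 - L + 1 for s, e in t.exons], dtype=float)
            exlens = np.clip(exlens, 0, None)
            if exlens.sum() == 0 or n_frag == 0:
                continue
            ex_choice = rng.choice(len(t.exons), size=n_frag, p=exlens / exlens.sum())
            which_hap = rng.integers(0, 2, size=n_frag)
            for j in range(n_frag):
                ex = t.exons[ex_choice[j]]
                vlist = exon_vars[row.gene_id][ex_choice[j]]
                start = ex[0] + int(rng.integers(0, ex[1] - ex[0] + 1 - L + 1))
                hap = hapA if which_hap[j] == 0 else hapB
                alleles = tuple(int(hap[vidx[v.vid]]) for v in vlist)
                key = (row.gene_id, ex_choice[j], alleles)
                hseq = hapseq_cache.get(key)
                if hseq is None:
                    hseq = _exon_haplotype_seq(
                        fixture.reference, ex, vlist, np.array(alleles, dtype=np.int8), t.contig
                    )
                    hapseq_cache[key] = hseq
                readseq = hseq[start - ex[0] : start - ex[0] + L]
                a = pysam.AlignedSegment(header)
                a.query_name = f"{sample}:{row.gene_id}:{j}"
                a.query_sequence = readseq
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                hit = _aligned(readseq)
                if hit is None:
                    a.is_unmapped = True
                else:
                    a.reference_id = tid[hit[0]]
                    a.reference_start = hit[1] - 1
                    a.mapping_quality = 37
                    a.cigarstring = f"{L}M"
                records.append(a)
        depth["total_fragments"] = n_frag_total
        depth_rows.append(depth)
        records.sort(key=lambda a: (a.is_unmapped, a.reference_id if not a.is_unmapped else 0,
                                    a.reference_start if not a.is_unmapped else 0))
        path = out_dir / f"{sample}.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for a in records:
                bam.write(a)
        bam_paths.append(path)
    return bam_paths, pd.DataFrame(depth_rows)


# ---------------------------------------------------------------------------
# file format writers / readers
# ---------------------------------------------------------------------------

def write_fasta(reference: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, build_index=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_vcf(panel: HaplotypePanel, reference: dict[str, str], path: str | Path) -> None:
    """Phased VCF v4.2 with per-record MAF in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in sorted(reference):
            fh.write(f"##contig=<ID={name},length={len(reference[name])}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        for j, v in enumerate(panel.variants):
            gts = "\t".join(
                f"{panel.haplotypes[2 * i, j]}|{panel.haplotypes[2 * i + 1, j]}"
                for i in range(panel.n_individuals)
            )
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.vid}\t{v.ref_seq}\t{v.alt_seq}\t.\tPASS\t"
                f"MAF={v.maf:.6f}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> HaplotypePanel:
    import pysam

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            maf = float(rec.info.get("MAF", 0.0))
            variants.append(
                VariantRecord(rec.id, rec.contig, rec.pos, rec.ref, rec.alts[0], maf)
            )
            col = np.empty(2 * len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                col[2 * i], col[2 * i + 1] = gt
            columns.append(col)
    return HaplotypePanel(variants, np.array(columns).T, samples)


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            s0, e0 = t.span
            fh.write(
                f"{t.contig}\tmapbias\ttranscript\t{s0}\t{e0}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(f"{t.contig}\tmapbias\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["contig", "source", "feature", "start", "end", "score", "strand", "frame", "attributes"],
    )
    exons = df[df.feature == "exon"].copy()
    exons["gene_id"] = exons["attributes"].str.extract(r'gene_id "([^"]+)"')
    exons["transcript_id"] = exons["attributes"].str.extract(r'transcript_id "([^"]+)"')
    out = []
    for (gid, tid), sub in exons.groupby(["gene_id", "transcript_id"], sort=True):
        sub = sub.sort_values("start")
        out.append(
            TranscriptModel(
                gid,
                tid,
                sub.contig.iloc[0],
                sub.strand.iloc[0],
                tuple(zip(sub.start.astype(int), sub.end.astype(int))),
            )
        )
    return out
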