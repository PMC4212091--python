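"""Generator contracts: determinism, conservation, planted structure."""

import numpy as np
import pandas as pd
import pytest

import mapbias as mb
from mapbias.synthetic import read_gtf, read_vcf, write_fasta, write_gtf, write_vcf


def test_variant_count_conservation_and_determinism(tmp_path):
    cfg = mb.SimulationConfig(rng_seed=1, genome_len=100_000, n_individuals=20)
    ref1, panel1 = mb.make_reference_panel(cfg, n_snps=200, n_indels=20)
    ref2, panel2 = mb.make_reference_panel(cfg, n_snps=200, n_indels=20)
    assert len(panel1.variants) == 220
    assert sum(v.vclass == "INDEL" for v in panel1.variants) == 20
    # byte-identical FASTA and VCF on re-run with the same seed
    for ref, panel, tag in [(ref1, panel1, "a"), (ref2, panel2, "b")]:
        write_fasta(ref, tmp_path / f"{tag}.fa")
        write_vcf(panel, ref, tmp_path / f"{tag}.vcf")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()


def test_segmental_duplications_present_by_substring_scan():
    cfg = mb.SimulationConfig(rng_seed=3, genome_len=50_000, n_individuals=10)
    ref, _ = mb.make_reference_panel(cfg, n_snps=10, dup_spec=[(500, 2)])
    seq = ref["chr1"]
    # brute-force: some 500-mer occurs (at least) 3 times (donor + 2 copies)
    probe_hits = 0
    for start in range(0, len(seq) - 500):
        probe = seq[start : start + 500]
        n = 0
        p = seq.find(probe)
        while p != -1:
            n += 1
            p = seq.find(probe, p + 1)
        if n >= 3:
            probe_hits += 1
            break
    assert probe_hits >= 1


def test_generator_rejections():
    cfg = mb.SimulationConfig(rng_seed=0, genome_len=10_000, n_individuals=10)
    with pytest.raises(ValueError):
        mb.make_reference_panel(cfg, n_snps=0, n_indels=0)
    with pytest.raises(ValueError):
        mb.make_reference_panel(cfg, n_snps=5, dup_spec=[(6000, 1)])


def test_every_variant_segregates(small_panel):
    _, panel = small_panel
    sums = panel.haplotypes.sum(axis=0)
    assert (sums > 0).all() and (sums < panel.haplotypes.shape[0]).all()


def test_maf_floor_respected(small_panel, small_cfg):
    _, panel = small_panel
    assert all(v.maf >= small_cfg.maf_min for v in panel.variants)


def test_vcf_roundtrip(tmp_path, small_panel):
    ref, panel = small_panel
    path = tmp_path / "panel.vcf"
    write_vcf(panel, ref, path)
    back = read_vcf(path)
    assert [v.vid for v in back.variants] == [v.vid for v in panel.variants]
    assert np.array_equal(back.haplotypes, panel.haplotypes)
    assert back.sample_ids == panel.sample_ids


def test_gtf_roundtrip(tmp_path, cohort_fixture):
    path = tmp_path / "genes.gtf"
    write_gtf(cohort_fixture.transcripts, path)
    back = read_gtf(path)
    assert {(t.gene_id, t.exons) for t in back} == {
        (t.gene_id, t.exons) for t in cohort_fixture.transcripts
    }


def test_planted_duplication_copies_alt_window(planted_panel, small_cfg):
    ref, panel, target, (contig, start, end) = planted_panel
    v = panel.variant(target)
    L = small_cfg.read_len
    alt_window = (
        ref[v.contig][v.pos - L : v.pos - 1] + v.alt_seq + ref[v.contig][v.pos : v.pos + L - 1]
    )
    assert ref[contig][start - 1 : end] == alt_window
    assert len(alt_window) == 2 * L - 1


def test_truth_table_rejects_bias_gene_with_effect():
    genes = pd.DataFrame(
        dict(gene_id=["g"], effect_class=["BIAS_FALSE_EQTL"], eqtl_variant=["v"], effect_size=[2.0])
    )
    with pytest.raises(ValueError):
        mb.TruthTable(genes=genes, variants=pd.DataFrame(dict(vid=["v"], planted_bias=[True])))


def test_cohort_fragment_conservation(tmp_path):
    """Every simulated fragment is written to the BAM, mapped or not."""
    import pysam

    cfg = mb.SimulationConfig(rng_seed=5, n_individuals=12)
    fx = mb.build_cohort_fixture(cfg, n_true=2, n_bias=1, n_null=2)
    bams, depth = mb.simulate_rnaseq_cohort(fx, tmp_path / "bams")
    depth = depth.set_index("individual")
    for bam in bams:
        with pysam.AlignmentFile(str(bam), "rb") as fh:
            n = sum(1 for _ in fh.fetch(until_eof=True))
        assert n == depth.loc[bam.stem, "total_fragments"]


def test_cohort_rejects_tiny_cohorts(tmp_path):
    cfg = mb.SimulationConfig(rng_seed=5, n_individuals=4)
    fx = mb.build_cohort_fixture(cfg, n_true=1, n_bias=0, n_null=1)
    with pytest.raises(ValueError):
        mb.simulate_rnaseq_cohort(fx, tmp_path / "bams")


def test_true_eqtl_homozygote_count_ratio(cohort_fixture, cohort_analysis):
    """Effect size 2 per alt allele gives a ~4-fold alt-hom/ref-hom mean."""
    dosage = cohort_fixture.panel.dosages()
    truth = cohort_fixture.truth.genes
    raw = cohort_analysis.matrix_before.counts
    hom_alt, hom_ref = [], []
    for row in truth[truth.effect_class == "TRUE_EQTL"].itertuples():
        d = dosage.loc[row.eqtl_variant]
        for exon in (f"{row.gene_id}:e0", f"{row.gene_id}:e1"):
            if exon not in raw.index:
                continue
            g0, g2 = d[d == 0].index, d[d == 2].index
            if len(g0) >= 3 and len(g2) >= 3:
                hom_ref.append(raw.loc[exon, g0].mean())
                hom_alt.append(raw.loc[exon, g2].mean())
    ratio = np.sum(hom_alt) / np.sum(hom_ref)
    assert 3.2 <= ratio <= 5.0


def test_bias_gene_true_fragment_counts_genotype_independent(cohort_fixture, tmp_path):
    """BIAS_FALSE_EQTL genes have effect_size 1: the *drawn* fragment
    depths are equal across genotypes before any mapping loss."""
    _, depth = mb.simulate_rnaseq_cohort(cohort_fixture, tmp_path / "bams")
    depth = depth.set_index("individual")
    dosage = cohort_fixture.panel.dosages()
    truth = cohort_fixture.truth.genes
    means = {0: [], 2: []}
    for row in truth[truth.effect_class == "BIAS_FALSE_EQTL"].itertuples():
        d = dosage.loc[row.eqtl_variant]
        for g in (0, 2):
            sel = d[d == g].index
            if len(sel) >= 2:
                means[g].append(depth.loc[sel, row.gene_id].mean())
    ratio = np.mean(means[2]) / np.mean(means[0])
    assert 0.8 <= ratio <= 1.25
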