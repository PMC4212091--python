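"""Built-in mapper: exhaustive-scan equivalence, tie handling, judgment."""

import shutil

import numpy as np
import pytest
from scipy import stats

import mapbias as mb
from mapbias.mapping import BuiltinMapper, judge_correctness, map_reads_external
from mapbias.reads import SimRead, revcomp

from oracles import scan_best_hits


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _sim(seq, contig="chr1", origin=1, allele="R", mate=None, mate_origin=None):
    return SimRead(
        focal_variant="v", origin_contig=contig, origin_start=origin,
        hap_signature=allele, focal_allele=allele, sequence=seq, frame="GENOME",
        window_variants=("v",), mate_sequence=mate, mate_origin_start=mate_origin,
    )


def test_exact_unique_read_maps_at_origin():
    ref = _random_seq(5000, seed=0)
    m = BuiltinMapper({"chr1": ref})
    res = m.align(ref[1000:1050])
    assert res.mapped and res.n_best_hits == 1 and res.pos == 1001 and res.mapq == 37
    assert judge_correctness(_sim(ref[1000:1050], origin=1001), res)


def test_duplicated_segment_read_multimaps():
    core = _random_seq(4000, seed=1)
    dup = core[500:700]
    ref = core + "ACGT" * 5 + dup  # exact second copy
    m = BuiltinMapper({"chr1": ref})
    res = m.align(ref[550:600])
    assert res.mapped and res.n_best_hits == 2 and res.mapq == 0
    assert not judge_correctness(_sim(ref[550:600], origin=551), res)


def test_builtin_reflexive_on_unique_substrings():
    ref = _random_seq(20_000, seed=2)
    m = BuiltinMapper({"chr1": ref})
    rng = np.random.default_rng(3)
    for p in rng.integers(0, len(ref) - 50, size=50):
        p = int(p)
        res = m.align(ref[p : p + 50])
        assert res.mapped and res.edit_distance == 0
        assert res.pos <= p + 1  # origin is among the best hits
        if res.n_best_hits == 1:
            assert res.pos == p + 1


def test_hits_equal_exhaustive_sliding_scan():
    """Seed-and-verify finds exactly the hits of a full banded DP scan,
    including all ties, for mutated reads."""
    ref = _random_seq(20_000, seed=4)
    m = BuiltinMapper({"chr1": ref})
    rng = np.random.default_rng(5)
    for _ in range(120):
        p = int(rng.integers(0, len(ref) - 60))
        read = list(ref[p : p + 55])
        for _ in range(int(rng.integers(0, 4))):
            q = int(rng.integers(0, 50))
            op = int(rng.integers(0, 3))
            if op == 0:
                read[q] = "ACGT"[int(rng.integers(0, 4))]
            elif op == 1:
                del read[q]
            else:
                read.insert(q, "ACGT"[int(rng.integers(0, 4))])
        read = "".join(read)[:50]
        best, hits = scan_best_hits(read, ref, 3)
        got = m._hits(read)
        if best is None:
            assert not got
            continue
        got_best = min(d for _, _, d in got)
        got_hits = {c + 1 for _, c, d in got if d == got_best}
        assert got_best == best and got_hits == hits


def test_unmapped_beyond_edit_budget():
    ref = _random_seq(5000, seed=6)
    m = BuiltinMapper({"chr1": ref})
    read = list(ref[100:150])
    for q in (5, 15, 25, 35):  # 4 substitutions > k=3
        read[q] = _flip(read[q])
    res = m.align("".join(read))
    assert not res.mapped


def test_position_tolerance_policy():
    ref = _random_seq(5000, seed=7)
    m = BuiltinMapper({"chr1": ref})
    res = m.align(ref[2000:2050])
    read = _sim(ref[2000:2050], origin=2002)  # recorded origin off by one
    assert not judge_correctness(read, res)
    assert judge_correctness(read, res, pos_tolerance=1)


def test_pair_rescue_of_multimapping_mate():
    """A mate that multi-maps alone is rescued by its uniquely mapping
    partner at the proper fragment span."""
    core = _random_seq(6000, seed=8)
    dup = core[1000:1100]  # copy mate-1's neighbourhood elsewhere
    ref = core + "TTTT" + dup
    m = BuiltinMapper({"chr1": ref})
    m1 = ref[1000:1050]
    assert m.align(m1).n_best_hits == 2
    start2 = 1050 + 60
    m2 = revcomp(ref[start2 : start2 + 50])
    pres = m.align_pair(m1, m2, inner_insert=60)
    assert pres.mapped and pres.n_best_pairs == 1
    assert pres.pos1 == 1001 and pres.pos2 == start2 + 1


def test_pair_with_no_valid_span_is_unmapped():
    ref = _random_seq(6000, seed=9)
    m = BuiltinMapper({"chr1": ref})
    m1 = ref[1000:1050]
    m2 = revcomp(ref[4000:4050])  # far beyond any plausible span
    assert not m.align_pair(m1, m2, inner_insert=60).mapped


@pytest.mark.skipif(shutil.which("bwa") is None, reason="bwa not on PATH")
def test_external_aligner_concordance(tmp_path):
    """Per-variant reference-allele ratios from the built-in mapper and
    BWA correlate strongly on a fixture with duplications and indels."""
    from mapbias.catalog import judge_reads, summarize_variant_bias
    from mapbias.pipeline import catalog_from_panel
    from mapbias.synthetic import write_fasta

    cfg = mb.SimulationConfig(rng_seed=21, genome_len=30_000, n_individuals=20)
    ref, panel = mb.make_reference_panel(cfg, n_snps=20, n_indels=10, dup_spec=[(400, 1)])
    # graded duplications: biased fraction of start sites varies per SNP
    snps = [v.vid for v in panel.variants if v.vclass == "SNP"]
    for i, vid in enumerate(snps[:10]):
        ref, _ = mb.plant_biased_duplication(ref, panel, vid, cfg, copy_len=54 + 5 * i)
    _, _, cat_builtin = catalog_from_panel(ref, panel, cfg)

    reads, _ = mb.build_simulated_reads(panel, ref, cfg)
    fq = tmp_path / "reads.fq"
    mb.write_fastq(reads, fq)
    fa = tmp_path / "ref.fa"
    write_fasta(ref, fa)
    cmd = (
        "bwa index {ref} 2>/dev/null && "
        "bwa aln {ref} {reads} 2>/dev/null > {ref}.sai && "
        "bwa samse {ref} {ref}.sai {reads} 2>/dev/null"
    )
    results = {r.read_id: r for r in map_reads_external(fq, fa, cmd, tmp_path)}
    judged = judge_reads(
        ((r, results[r.read_id]) for r in reads),
        {v.vid: v.vclass for v in panel.variants},
    )
    cat_bwa = summarize_variant_bias(judged)
    merged = cat_builtin.merge(cat_bwa, on="variant").dropna(
        subset=["ref_ratio_x", "ref_ratio_y"]
    )
    rho = stats.spearmanr(merged.ref_ratio_x, merged.ref_ratio_y).statistic
    assert rho >= 0.9


def _flip(b):
    return "ACGT"[("ACGT".index(b) + 1) % 4]
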