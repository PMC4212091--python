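"""Read enumeration: window math, observed haplotypes, oracle equality."""

import numpy as np
import pytest

import mapbias as mb
from mapbias.reads import (
    SplicedTranscript,
    build_simulated_reads,
    enumerate_read_windows,
    local_haplotypes,
    revcomp,
)
from mapbias.synthetic import HaplotypePanel, TranscriptModel, VariantRecord

from oracles import brute_force_read_set


def _snp(vid, pos, contig="chr1", ref="A", alt="C"):
    return VariantRecord(vid, contig, pos, ref, alt, 0.3)


@pytest.mark.parametrize(
    "variant,read_len,contig_len,expected",
    [
        (_snp("v", 100), 50, 10_000, list(range(51, 101))),   # L windows over a SNP
        (_snp("v", 10), 50, 10_000, list(range(1, 11))),      # truncated at contig start
        (VariantRecord("d", "chr1", 100, "AGGG", "A", 0.2), 50, 10_000,
         list(range(51, 104))),                               # footprint 100..103
        (_snp("v", 30), 50, 40, []),                          # contig shorter than read
    ],
)
def test_enumerate_read_windows(variant, read_len, contig_len, expected):
    got = enumerate_read_windows(variant, read_len, contig_len)
    # brute-force re-derivation: every start whose window intersects the footprint
    brute = [
        s
        for s in range(1, max(0, contig_len - read_len + 1) + 1)
        if s <= variant.end and s + read_len - 1 >= variant.pos
    ]
    assert got == brute == expected


def test_local_haplotypes_observed_combinations_only():
    # two variants with only RR / AA chromosomes observed
    variants = [_snp("a", 100), _snp("b", 110, ref="G", alt="T")]
    haps = np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=np.int8)
    panel = HaplotypePanel(variants, haps, ["s1", "s2"])
    assert local_haplotypes(panel, ["a", "b"]) == {"RR", "AA"}


def test_local_haplotypes_includes_all_reference():
    variants = [_snp("a", 100), _snp("b", 110, ref="G", alt="T")]
    haps = np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=np.int8)  # no RR row
    panel = HaplotypePanel(variants, haps, ["s1", "s2"])
    assert local_haplotypes(panel, ["a", "b"]) == {"AA", "AR", "RR"}


def test_local_haplotypes_matches_brute_force_restriction(rng):
    n_var, n_hap = 6, 30
    variants = [_snp(f"v{i}", 100 + 7 * i) for i in range(n_var)]
    haps = (rng.random((n_hap, n_var)) < 0.4).astype(np.int8)
    panel = HaplotypePanel(variants, haps, [f"s{i}" for i in range(n_hap // 2)])
    for subset in ([0, 1], [2, 3, 4], [0, 5]):
        vids = [variants[i].vid for i in subset]
        brute = {"".join("RA"[x] for x in row[subset]) for row in haps}
        brute.add("R" * len(subset))
        assert local_haplotypes(panel, vids) == brute


def test_isolated_snp_yields_two_reads_per_window(small_cfg):
    seq = _random_seq(2000, seed=5)
    v = VariantRecord("v0", "chr1", 1000, seq[999], _other(seq[999]), 0.3)
    panel = HaplotypePanel([v], np.array([[0], [1]], dtype=np.int8), ["s0"])
    reads, skipped = build_simulated_reads(panel, {"chr1": seq}, small_cfg)
    assert skipped == 0
    assert len(reads) == 2 * small_cfg.read_len
    assert len({r.read_id for r in reads}) == len(reads)
    # sequences equal independent substitution of the reference window
    for r in reads:
        window = seq[r.origin_start - 1 : r.origin_start - 1 + 50]
        if r.focal_allele == "A":
            off = 1000 - r.origin_start
            window = window[:off] + v.alt_seq + window[off + 1 :]
        assert r.sequence == window


def test_read_set_equals_brute_force_enumeration():
    for seed in (0, 1, 2):
        cfg = mb.SimulationConfig(rng_seed=seed, genome_len=6_000, n_individuals=8)
        ref, panel = mb.make_reference_panel(cfg, n_snps=8, n_indels=4)
        reads, _ = build_simulated_reads(panel, ref, cfg)
        got = {
            (r.focal_variant, r.origin_contig, r.origin_start, r.hap_signature,
             r.focal_allele, r.sequence)
            for r in reads
        }
        assert got == brute_force_read_set(panel, ref, cfg.read_len)


def test_transcript_reads_span_junctions(small_cfg):
    seq = _random_seq(3000, seed=9)
    t = TranscriptModel("g", "g.t", "chr1", "+", ((1001, 1100), (1501, 1600)))
    # SNP 10 bp before the junction (transcript coords 91)
    pos = 1091
    v = VariantRecord("v0", "chr1", pos, seq[pos - 1], _other(seq[pos - 1]), 0.3)
    panel = HaplotypePanel([v], np.array([[0], [1]], dtype=np.int8), ["s0"])
    reads, _ = build_simulated_reads(
        panel, {"chr1": seq}, small_cfg, mode="TRANSCRIPT_SE", transcripts=[t]
    )
    st = SplicedTranscript(t, {"chr1": seq})
    spliced = seq[1000:1100] + seq[1500:1600]
    junction_reads = [r for r in reads if r.transcript_start + 49 > 100]
    assert junction_reads, "reads must cross the junction"
    for r in reads:
        # transcript-frame sequence equals a naive splice substitution
        tpos = r.transcript_start - 1
        expect = spliced[tpos : tpos + 50]
        if r.focal_allele == "A":
            off = 90 - tpos  # SNP at transcript offset 90 (0-based)
            expect = expect[:off] + v.alt_seq + expect[off + 1 :]
        assert r.sequence == expect
        # genomic projection splits across exons exactly at the junction
        intervals = st.genomic_intervals(tpos, 50)
        assert sum(e - s + 1 for s, e in intervals) == 50
        if tpos + 50 > 100 and tpos < 100:
            assert len(intervals) == 2
            assert intervals[0][1] == 1100 and intervals[1][0] == 1501
        assert r.origin_start == intervals[0][0]


def test_paired_end_mate2_constant_when_no_variant_in_window(small_cfg):
    seq = _random_seq(3000, seed=3)
    v = VariantRecord("v0", "chr1", 1000, seq[999], _other(seq[999]), 0.3)
    panel = HaplotypePanel([v], np.array([[0], [1]], dtype=np.int8), ["s0"])
    reads, _ = build_simulated_reads(panel, {"chr1": seq}, small_cfg, mode="GENOME_PE")
    by_start = {}
    for r in reads:
        by_start.setdefault(r.origin_start, []).append(r)
    assert all(len(v) == 2 for v in by_start.values())
    for s, pair in by_start.items():
        m1, m2 = pair
        assert m1.mate_sequence == m2.mate_sequence  # mate 2 has no variant
        assert m1.mate_origin_start == s + 50 + small_cfg.inner_insert
        expect = seq[m1.mate_origin_start - 1 : m1.mate_origin_start + 49]
        assert m1.mate_sequence == revcomp(expect)


def test_mode_validation(small_panel, small_cfg):
    ref, panel = small_panel
    with pytest.raises(ValueError):
        build_simulated_reads(panel, ref, small_cfg, mode="BOGUS")
    with pytest.raises(ValueError):
        build_simulated_reads(panel, ref, small_cfg, mode="TRANSCRIPT_SE")


def test_fastq_roundtrip(tmp_path, small_cfg):
    seq = _random_seq(1000, seed=1)
    v = VariantRecord("v0", "chr1", 500, seq[499], _other(seq[499]), 0.3)
    panel = HaplotypePanel([v], np.array([[0], [1]], dtype=np.int8), ["s0"])
    reads, _ = build_simulated_reads(panel, {"chr1": seq}, small_cfg)
    path = tmp_path / "reads.fq"
    n = mb.write_fastq(reads, path)
    back = list(mb.reads.iter_fastq(path))
    assert n == len(back) == len(reads)
    assert back[0][0] == reads[0].read_id and back[0][1] == reads[0].sequence


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _other(base):
    return "ACGT"[("ACGT".index(base) + 1) % 4]
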