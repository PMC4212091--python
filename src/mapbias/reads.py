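"""Exhaustive enumeration of potential reads over every variant.

For each variant in the panel, every read window that overlaps the
variant's footprint is generated once per *observed* local haplotype —
the distinct combinations of alleles, over the variants inside the
window, seen on at least one panel chromosome (plus the all-reference
combination).  Haplotype combinations are used in equal proportions
regardless of their population frequency: one read per combination.

Three modes:

* GENOME_SE   — single-end reads from the genome sequence;
* TRANSCRIPT_SE — single-end reads from spliced transcript sequence,
  for variants fully inside annotated exons (reads can span splice
  junctions);
* GENOME_PE   — paired-end reads: mate 1 as in GENOME_SE, mate 2 the
  reverse complement of the window starting ``inner_insert`` bases
  after mate 1's end on the same haplotype.

Windows are anchored in haplotype coordinates; the recorded origin of
a read is the reference coordinate of its first aligned base under a
left-normalized projection (an indel's inserted bases project to the
indel's anchor position, deleted bases to the next retained base).
Reads are simulated on the forward strand only: end-to-end alignment
of a read and of its reverse complement is symmetric, so the reverse
strand adds no information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .synthetic import HaplotypePanel, SimulationConfig, TranscriptModel, VariantRecord

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimRead:
    """One simulated read (or pair) with its provenance.

    origin_start is the 1-based reference coordinate of the first
    aligned base (for TRANSCRIPT frame: the genomic projection);
    mate_origin_start likewise for mate 2 of a pair.  hap_signature is
    the R/A allele string over the variants inside the read window(s),
    in panel order; focal_allele is its entry at the focal variant.
    """

    focal_variant: str
    origin_contig: str
    origin_start: int
    hap_signature: str
    focal_allele: str  # 'R' | 'A'
    sequence: str
    frame: str  # 'GENOME' | 'TRANSCRIPT'
    window_variants: tuple[str, ...]
    mate_sequence: str | None = None
    mate_origin_start: int | None = None
    transcript_id: str | None = None
    transcript_start: int | None = None

    @property
    def read_id(self) -> str:
        rid = (
            f"v={self.focal_variant};c={self.origin_contig};s={self.origin_start};"
            f"h={self.hap_signature};a={self.focal_allele};"
            f"f={'T' if self.frame == 'TRANSCRIPT' else 'G'}"
        )
        if self.transcript_id is not None:
            rid += f";t={self.transcript_id};ts={self.transcript_start}"
        if self.mate_origin_start is not None:
            rid += f";m={self.mate_origin_start}"
        return rid


# ---------------------------------------------------------------------------
# window enumeration and haplotype restriction
# ---------------------------------------------------------------------------

def enumerate_read_windows(variant: VariantRecord, read_len: int, contig_len: int) -> list[int]:
    """All 1-based window starts s with [s, s+read_len-1] intersecting
    the variant footprint and fully inside the contig, ascending."""
    if contig_len < read_len:
        return []
    lo = max(1, variant.pos - read_len + 1)
    hi = min(variant.end, contig_len - read_len + 1)
    return list(range(lo, hi + 1))


def local_haplotypes(panel: HaplotypePanel, window_variants: list[str]) -> set[str]:
    """Distinct observed allele strings over the given variants.

    Restrictions of the panel's chromosomes to the window, each counted
    once; the all-reference string is always included.
    """
    if not window_variants:
        return {""}
    cols = np.column_stack([panel.column(v) for v in window_variants])
    sigs = {"".join("RA"[a] for a in row) for row in cols}
    sigs.add("R" * len(window_variants))
    return sigs


# ---------------------------------------------------------------------------
# haplotype substitution with coordinate projection
# ---------------------------------------------------------------------------

class HaplotypeRegion:
    """A reference region with a subset of variant alt alleles applied.

    Provides the substituted sequence and both projections between
    reference coordinates (1-based, global) and haplotype offsets
    (0-based within the region).
    """

    def __init__(
        self,
        ref_seq: str,
        region_start: int,
        region_end: int,
        variants: list[VariantRecord],
        alleles: Iterable[int],
    ) -> None:
        a, b = region_start, region_end
        out: list[str] = []
        ref2hap = np.empty(b - a + 1, dtype=np.int64)
        hap2ref: list[int] = []
        footprints: dict[str, tuple[int, int]] = {}
        cur = a
        for v, al in zip(variants, alleles):
            if v.pos < a or v.end > b:
                raise ValueError(f"variant {v.vid} outside region")
            for p in range(cur, v.pos):
                ref2hap[p - a] = len(out)
                hap2ref.append(p)
                out.append(ref_seq[p - 1])
            seq = v.alt_seq if al else v.ref_seq
            start_idx = len(out)
            ref2hap[v.pos - a] = start_idx
            for ch in seq:
                hap2ref.append(v.pos)
                out.append(ch)
            footprints[v.vid] = (start_idx, len(out) - 1)
            # deleted interior reference bases project to the next
            # retained haplotype base (left-normalized convention)
            for p in range(v.pos + 1, v.end + 1):
                ref2hap[p - a] = len(out)
            cur = v.end + 1
        for p in range(cur, b + 1):
            ref2hap[p - a] = len(out)
            hap2ref.append(p)
            out.append(ref_seq[p - 1])
        self.region_start = a
        self.region_end = b
        self.seq = "".join(out)
        self._ref2hap = ref2hap
        self._hap2ref = np.array(hap2ref, dtype=np.int64)
        self.footprints = footprints

    def ref2hap(self, pos: int) -> int:
        return int(self._ref2hap[pos - self.region_start])

    def hap2ref(self, offset: int) -> int:
        return int(self._hap2ref[offset])


# ---------------------------------------------------------------------------
# read construction
# ---------------------------------------------------------------------------

def _neighbourhood(
    panel: HaplotypePanel, focal: VariantRecord, read_len: int, margin: int
) -> list[tuple[int, VariantRecord]]:
    """Indices+records of variants whose footprint can share a fragment
    window with the focal variant (same contig, within margin bases)."""
    out = []
    for j, v in enumerate(panel.variants):
        if v.contig == focal.contig and v.end >= focal.pos - margin and v.pos <= focal.end + margin:
            out.append((j, v))
    return out


def _distinct_rows(panel: HaplotypePanel, idx: list[int]) -> list[tuple[int, ...]]:
    cols = panel.haplotypes[:, idx]
    rows = {tuple(int(x) for x in r) for r in cols}
    rows.add(tuple([0] * len(idx)))
    return sorted(rows)


def build_simulated_reads(
    panel: HaplotypePanel,
    reference: dict[str, str],
    config: SimulationConfig,
    mode: str = "GENOME_SE",
    transcripts: list[TranscriptModel] | None = None,
) -> tuple[list[SimRead], int]:
    """Enumerate all potential reads; returns (reads, n_skipped).

    Skipped windows are those extending past contig or transcript ends
    (paired-end fragments additionally require room for the mate).
    """
    if mode not in ("GENOME_SE", "TRANSCRIPT_SE", "GENOME_PE"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "TRANSCRIPT_SE":
        if transcripts is None:
            raise ValueError("TRANSCRIPT_SE requires transcripts")
        return _build_transcript_reads(panel, reference, config, transcripts)

    L = config.read_len
    paired = mode == "GENOME_PE"
    frag_extra = L + config.inner_insert if paired else 0
    margin = L + frag_extra + 60
    reads: list[SimRead] = []
    skipped = 0
    seen: set[str] = set()
    for focal in panel.variants:
        contig_seq = reference[focal.contig]
        clen = len(contig_seq)
        nb = _neighbourhood(panel, focal, L, margin)
        nb_idx = [j for j, _ in nb]
        nb_vars = [v for _, v in nb]
        focal_nb = nb_vars.index(focal)
        region_a = max(1, min(v.pos for v in nb_vars) - margin)
        region_b = min(clen, max(v.end for v in nb_vars) + margin)
        windows = enumerate_read_windows(focal, L, clen)
        for row in _distinct_rows(panel, nb_idx):
            region = HaplotypeRegion(contig_seq, region_a, region_b, nb_vars, row)
            focal_allele = "RA"[row[focal_nb]]
            for s in windows:
                h = region.ref2hap(s)
                seq = region.seq[h : h + L]
                if len(seq) < L:
                    skipped += 1
                    continue
                mate_seq = None
                mate_origin = None
                if paired:
                    h2 = h + L + config.inner_insert
                    m = region.seq[h2 : h2 + L]
                    if len(m) < L:
                        skipped += 1
                        continue
                    mate_seq = revcomp(m)
                if paired:
                    h_span_end = h + 2 * L + config.inner_insert - 1
                else:
                    h_span_end = h + L - 1
                sig, wvids = _fragment_signature(
                    region, nb_vars, row, h, h_span_end, focal.vid
                )
                origin = region.hap2ref(h)
                if paired:
                    mate_origin = region.hap2ref(h + L + config.inner_insert)
                read = SimRead(
                    focal_variant=focal.vid,
                    origin_contig=focal.contig,
                    origin_start=origin,
                    hap_signature=sig,
                    focal_allele=focal_allele,
                    sequence=seq,
                    frame="GENOME",
                    window_variants=wvids,
                    mate_sequence=mate_seq,
                    mate_origin_start=mate_origin,
                )
                if read.read_id in seen:
                    continue  # same window content via a duplicate local haplotype
                seen.add(read.read_id)
                reads.append(read)
    return reads, skipped


def _fragment_signature(
    region: HaplotypeRegion,
    nb_variants: list[VariantRecord],
    alleles: tuple[int, ...],
    h_start: int,
    h_end: int,
    focal_vid: str,
) -> tuple[str, tuple[str, ...]]:
    sig = []
    vids = []
    for v, al in zip(nb_variants, alleles):
        fs, fe = region.footprints[v.vid]
        if (fs <= h_end and fe >= h_start) or v.vid == focal_vid:
            sig.append("RA"[al])
            vids.append(v.vid)
    return "".join(sig), tuple(vids)


# ---------------------------------------------------------------------------
# transcript-frame reads
# ---------------------------------------------------------------------------

class SplicedTranscript:
    """Spliced (exon-concatenated) sequence with coordinate projections."""

    def __init__(self, model: TranscriptModel, reference: dict[str, str]) -> None:
        self.model = model
        seq = reference[model.contig]
        parts = []
        g2t: dict[int, int] = {}
        t2g: list[int] = []
        off = 0
        for s, e in model.exons:
            parts.append(seq[s - 1 : e])
            for p in range(s, e + 1):
                g2t[p] = off
                t2g.append(p)
                off += 1
        self.seq = "".join(parts)
        self._g2t = g2t
        self._t2g = np.array(t2g, dtype=np.int64)

    def genome_to_transcript(self, pos: int) -> int | None:
        return self._g2t.get(pos)

    def transcript_to_genome(self, offset: int) -> int:
        return int(self._t2g[offset])

    def contains_variant(self, v: VariantRecord) -> bool:
        """Variant footprint fully inside a single exon."""
        return any(s <= v.pos and v.end <= e for s, e in self.model.exons)

    def genomic_intervals(self, t_start: int, length: int) -> list[tuple[int, int]]:
        """Split genomic intervals covered by a transcript window."""
        pos = self._t2g[t_start : t_start + length]
        out: list[tuple[int, int]] = []
        for p in pos:
            p = int(p)
            if out and p == out[-1][1] + 1:
                out[-1] = (out[-1][0], p)
            else:
                out.append((p, p))
        return out


def _build_transcript_reads(
    panel: HaplotypePanel,
    reference: dict[str, str],
    config: SimulationConfig,
    transcripts: list[TranscriptModel],
) -> tuple[list[SimRead], int]:
    """TRANSCRIPT_SE: enumerate over spliced sequence.

    Each transcript's exonic variants are projected to transcript
    coordinates and the genome-frame machinery is reused on the spliced
    sequence; recorded origins carry both the transcript coordinate and
    the projected genomic coordinate of the first aligned base.
    """
    L = config.read_len
    reads: list[SimRead] = []
    skipped = 0
    seen: set[str] = set()
    vindex = {v.vid: j for j, v in enumerate(panel.variants)}
    for model in transcripts:
        st = SplicedTranscript(model, reference)
        tvars: list[VariantRecord] = []
        for v in panel.variants:
            if v.contig != model.contig or not st.contains_variant(v):
                continue
            tpos = st.genome_to_transcript(v.pos)
            tvars.append(
                VariantRecord(v.vid, model.transcript_id, tpos + 1, v.ref_seq, v.alt_seq, v.maf)
            )
        if not tvars:
            continue
        tlen = len(st.seq)
        for focal in tvars:
            nb = [w for w in tvars if w.end >= focal.pos - (L + 60) and w.pos <= focal.end + (L + 60)]
            nb_idx = [vindex[w.vid] for w in nb]
            focal_nb = [w.vid for w in nb].index(focal.vid)
            region_a = max(1, min(w.pos for w in nb) - (L + 60))
            region_b = min(tlen, max(w.end for w in nb) + (L + 60))
            windows = enumerate_read_windows(focal, L, tlen)
            for row in _distinct_rows(panel, nb_idx):
                region = HaplotypeRegion(st.seq, region_a, region_b, nb, row)
                focal_allele = "RA"[row[focal_nb]]
                for s in windows:
                    h = region.ref2hap(s)
                    seq = region.seq[h : h + L]
                    if len(seq) < L:
                        skipped += 1
                        continue
                    sig, wvids = _fragment_signature(region, nb, row, h, h + L - 1, focal.vid)
                    t_start = region.hap2ref(h)  # transcript coordinate, 1-based
                    g_start = st.transcript_to_genome(t_start - 1)
                    read = SimRead(
                        focal_variant=focal.vid,
                        origin_contig=model.contig,
                        origin_start=g_start,
                        hap_signature=sig,
                        focal_allele=focal_allele,
                        sequence=seq,
                        frame="TRANSCRIPT",
                        window_variants=wvids,
                        transcript_id=model.transcript_id,
                        transcript_start=t_start,
                    )
                    if read.read_id in seen:
                        continue
                    seen.add(read.read_id)
                    reads.append(read)
    return reads, skipped


# ---------------------------------------------------------------------------
# FASTQ output
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[SimRead], path: str | Path, mate: int = 0) -> int:
    """Write reads (or one mate of pairs) as FASTQ with fixed quality.

    mate=0 writes single-end sequences, mate=1/2 the respective mate of
    paired reads.  Returns the number of records written.
    """
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            seq = r.sequence if mate in (0, 1) else r.mate_sequence
            if seq is None:
                continue
            fh.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        while True:
            name = fh.readline().strip()
            if not name:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield name[1:], seq
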