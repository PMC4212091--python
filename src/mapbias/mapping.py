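"""Deterministic read mapping and per-read correctness judgment.

The built-in mapper finds *every* end-to-end alignment of a read with
edit distance <= k (default 3 for 50 bp, approximating the missing-data
tolerance of short-read aligners of the BWA generation).  Candidate
start positions come from a pigeonhole seed scheme — the read is split
into k+1 segments, at least one of which must match exactly in any
alignment within budget — and each candidate start is scored with a
prefix-anchored (SHW) edit-distance computation.  Ties are enumerated
exhaustively, never sampled, so n_best_hits is exact and every run is
deterministic.

A read is judged *correct* only if it maps, uniquely, to exactly its
recorded origin.  Unmapped, mismapped and multi-mapped reads are all
treated as incorrect: any of the three makes reads carrying different
alleles map unequally, which is the bias mechanism being cataloged.

An external aligner can stand in for the built-in one through a shell
command template producing SAM; best-hit counts are taken from BWA's
X0 tag when present, else inferred from MAPQ 0.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import edlib

from .reads import SimRead, revcomp

DEFAULT_K = 3
UNIQUE_MAPQ = 37


@dataclass(frozen=True)
class AlignmentResult:
    read_id: str
    mapped: bool
    contig: str | None = None
    pos: int | None = None  # 1-based leftmost
    mapq: int = 0
    n_best_hits: int = 0
    edit_distance: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.mapped and self.n_best_hits < 1:
            raise ValueError("mapped result needs n_best_hits >= 1")


@dataclass(frozen=True)
class PairAlignmentResult:
    read_id: str
    mapped: bool
    contig: str | None = None
    pos1: int | None = None
    pos2: int | None = None
    n_best_pairs: int = 0
    score: int | None = None  # summed edit distance


class BuiltinMapper:
    """Exhaustive seed-and-verify mapper over an in-memory reference."""

    def __init__(self, reference: dict[str, str], k: int = DEFAULT_K, seed_len: int = 12):
        self.reference = reference
        self.k = k
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[int, int]]] = {}
        self._contigs = sorted(reference)
        for ci, name in enumerate(self._contigs):
            seq = reference[name]
            for p in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[p : p + seed_len], []).append((ci, p))

    # -- candidate generation ------------------------------------------------

    def _candidates(self, seq: str) -> set[tuple[int, int]]:
        """0-based candidate (contig_idx, start) positions.

        Pigeonhole: split the read into k+1 segments; an alignment with
        <= k edits leaves at least one segment edit-free, whose prefix
        seed then occurs exactly in the reference on a diagonal within
        +-k of the alignment start.
        """
        L = len(seq)
        n_seg = self.k + 1
        offsets = [round(i * L / n_seg) for i in range(n_seg)]
        cands: set[tuple[int, int]] = set()
        for off in offsets:
            seed = seq[off : off + self.seed_len]
            if len(seed) < self.seed_len:
                continue
            for ci, p in self._index.get(seed, ()):
                base = p - off
                for shift in range(-self.k, self.k + 1):
                    cands.add((ci, base + shift))
        return cands

    def _hits(self, seq: str) -> list[tuple[int, int, int]]:
        """All (contig_idx, start0, distance) with distance <= k."""
        L = len(seq)
        out = []
        for ci, c in self._candidates(seq):
            if c < 0:
                continue
            ref = self.reference[self._contigs[ci]]
            if c >= len(ref):
                continue
            target = ref[c : c + L + self.k]
            if len(target) < L - self.k:
                continue
            d = edlib.align(seq, target, mode="SHW", k=self.k)["editDistance"]
            if d != -1:
                out.append((ci, c, d))
        return out

    # -- public API ----------------------------------------------------------

    def align(self, seq: str, read_id: str = "", both_strands: bool = False) -> AlignmentResult:
        """Best alignment(s) of a read; exact tie counting.

        With both_strands the reverse complement is searched too and
        the reported position is the leftmost base of the reverse-
        strand alignment window.
        """
        hits = [(ci, c, d, "+") for ci, c, d in self._hits(seq)]
        if both_strands:
            hits += [(ci, c, d, "-") for ci, c, d in self._hits(revcomp(seq))]
        if not hits:
            return AlignmentResult(read_id, mapped=False)
        best = min(h[2] for h in hits)
        best_hits = sorted(set((ci, c, st) for ci, c, d, st in hits if d == best))
        ci, c, strand = best_hits[0]
        return AlignmentResult(
            read_id=read_id,
            mapped=True,
            contig=self._contigs[ci],
            pos=c + 1,
            mapq=0 if len(best_hits) > 1 else UNIQUE_MAPQ,
            n_best_hits=len(best_hits),
            edit_distance=best,
            strand=strand,
        )

    def align_pair(
        self,
        seq1: str,
        seq2: str,
        inner_insert: int,
        read_id: str = "",
        span_tol: int | None = None,
    ) -> PairAlignmentResult:
        """Resolve a forward/reverse pair jointly.

        Mate 2 is reverse-complemented and both mates are aligned on
        the forward strand; a valid pairing places mate 2's window
        len(seq1) + inner_insert bases after mate 1's start on the same
        contig (within span_tol, default 2k, absorbing indel shifts).
        The best pairing minimizes the summed edit distance; ties are
        counted.  Pairs with no valid pairing are reported unmapped.
        """
        tol = 2 * self.k if span_tol is None else span_tol
        h1 = self._hits(seq1)
        h2 = self._hits(revcomp(seq2))
        expected = len(seq1) + inner_insert
        pairs = []
        for ci1, c1, d1 in h1:
            for ci2, c2, d2 in h2:
                if ci1 == ci2 and abs((c2 - c1) - expected) <= tol:
                    pairs.append((ci1, c1, c2, d1 + d2))
        if not pairs:
            return PairAlignmentResult(read_id, mapped=False)
        best = min(p[3] for p in pairs)
        best_pairs = sorted(set((ci, c1, c2) for ci, c1, c2, s in pairs if s == best))
        ci, c1, c2 = best_pairs[0]
        return PairAlignmentResult(
            read_id=read_id,
            mapped=True,
            contig=self._contigs[ci],
            pos1=c1 + 1,
            pos2=c2 + 1,
            n_best_pairs=len(best_pairs),
            score=best,
        )


def map_reads(
    reads: Iterable[SimRead],
    mapper: BuiltinMapper,
    inner_insert: int | None = None,
) -> Iterator[tuple[SimRead, AlignmentResult | PairAlignmentResult]]:
    """Map simulated reads (single or paired) with the built-in mapper.

    Alignment results are memoized on the read sequence: reads that are
    textually identical (the same start site reached through different
    focal variants) are mapped once, as in unique-start-site
    accounting.
    """
    cache: dict = {}
    for r in reads:
        if r.mate_sequence is None:
            key = r.sequence
            res = cache.get(key)
            if res is None:
                res = mapper.align(r.sequence)
                cache[key] = res
        else:
            key = (r.sequence, r.mate_sequence)
            res = cache.get(key)
            if res is None:
                ins = inner_insert if inner_insert is not None else 60
                res = mapper.align_pair(r.sequence, r.mate_sequence, ins)
                cache[key] = res
        yield r, res


# ---------------------------------------------------------------------------
# correctness judgment
# ---------------------------------------------------------------------------

def judge_correctness(
    sim_read: SimRead,
    aln: AlignmentResult,
    pos_tolerance: int = 0,
) -> bool:
    """True iff the read mapped uniquely back to its origin.

    Requires mapped, a single best hit, positive mapping quality, and
    the reported leftmost position matching the recorded origin (the
    genomic projection of the first aligned base for transcript-frame
    reads).  ``pos_tolerance`` admits aligner left-shift ambiguity
    around indels.
    """
    if not aln.mapped or aln.n_best_hits != 1 or aln.mapq < 1:
        return False
    if aln.contig != sim_read.origin_contig:
        return False
    return abs(aln.pos - sim_read.origin_start) <= pos_tolerance


def judge_pair_correctness(
    sim_read: SimRead,
    aln: PairAlignmentResult,
    pos_tolerance: int = 0,
) -> bool:
    """Both mates of the unique best pairing at their origins."""
    if not aln.mapped or aln.n_best_pairs != 1:
        return False
    if aln.contig != sim_read.origin_contig:
        return False
    return (
        abs(aln.pos1 - sim_read.origin_start) <= pos_tolerance
        and abs(aln.pos2 - sim_read.mate_origin_start) <= pos_tolerance
    )


# ---------------------------------------------------------------------------
# transcript-frame mapping against a joint genome + transcriptome index
# ---------------------------------------------------------------------------

class JointIndexMapper:
    """Maps transcript-frame reads against genome plus spliced contigs.

    Junction-spanning reads can only match the transcript contig;
    exon-internal reads match both the genome and the transcript, which
    is the same origin seen twice, so hits are collapsed by their
    projected genomic first-base before counting.
    """

    def __init__(self, reference: dict[str, str], spliced: dict[str, "object"], k: int = DEFAULT_K):
        joint = dict(reference)
        self._spliced = spliced  # transcript_id -> SplicedTranscript
        for tid_, st in spliced.items():
            joint[f"__tx__{tid_}"] = st.seq
        self._mapper = BuiltinMapper(joint, k=k)

    def align(self, seq: str, read_id: str = "") -> AlignmentResult:
        hits = self._mapper._hits(seq)
        if not hits:
            return AlignmentResult(read_id, mapped=False)
        best = min(h[2] for h in hits)
        projected: set[tuple[str, int]] = set()
        for ci, c, d in hits:
            if d != best:
                continue
            name = self._mapper._contigs[ci]
            if name.startswith("__tx__"):
                st = self._spliced[name[len("__tx__"):]]
                if c >= len(st.seq):
                    continue
                projected.add((st.model.contig, st.transcript_to_genome(c)))
            else:
                projected.add((name, c + 1))
        contig, pos = sorted(projected)[0]
        n = len(projected)
        return AlignmentResult(
            read_id=read_id,
            mapped=True,
            contig=contig,
            pos=pos,
            mapq=0 if n > 1 else UNIQUE_MAPQ,
            n_best_hits=n,
            edit_distance=best,
        )


# ---------------------------------------------------------------------------
# external aligner adapter
# ---------------------------------------------------------------------------

def map_reads_external(
    fastq: str | Path,
    reference_fasta: str | Path,
    command_template: str,
    workdir: str | Path,
) -> list[AlignmentResult]:
    """Run an external aligner and parse its SAM output.

    ``command_template`` is a shell snippet with ``{reads}`` and
    ``{ref}`` placeholders that must write SAM to stdout (e.g. a
    bwa aln | bwa samse pipeline).  n_best_hits uses the X0 tag when
    the aligner emits it, else MAPQ 0 is taken to mean multiple best
    hits.
    """
    import pysam

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    sam_path = workdir / "external.sam"
    cmd = command_template.format(reads=shlex.quote(str(fastq)), ref=shlex.quote(str(reference_fasta)))
    with open(sam_path, "w") as out:
        proc = subprocess.run(
            ["bash", "-c", cmd], stdout=out, stderr=subprocess.PIPE, text=True
        )
    if proc.returncode != 0:
        raise RuntimeError(f"external aligner failed:\n{proc.stderr[-2000:]}")
    results = []
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                results.append(AlignmentResult(rec.query_name, mapped=False))
                continue
            if rec.has_tag("X0"):
                n_best = int(rec.get_tag("X0"))
            else:
                n_best = 2 if rec.mapping_quality == 0 else 1
            results.append(
                AlignmentResult(
                    read_id=rec.query_name,
                    mapped=True,
                    contig=rec.reference_name,
                    pos=rec.reference_start + 1,
                    mapq=rec.mapping_quality,
                    n_best_hits=max(1, n_best),
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return results
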