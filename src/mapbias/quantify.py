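"""Exon-level expression quantification and normalization.

A read increments an exon iff its leftmost aligned base falls inside
the exon interval (consistent with start-site-based filtering), and is
counted at most once.  Exon presence filtering keeps exons with >0
reads in strictly more than a given fraction of individuals, and
normalization scales each individual by its total exon-mapped read
count; optional covariates are regressed out of log counts.  Because
the downstream association test is rank-based, any strictly monotone
per-individual transform of the normalized values leaves eQTL P values
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .synthetic import TranscriptModel, read_gtf


@dataclass
class ExonCountMatrix:
    """Exons x individuals counts with exon metadata.

    ``counts`` is indexed by exon id; ``exons`` maps exon id ->
    (gene_id, contig, start, end).
    """

    counts: pd.DataFrame
    exons: pd.DataFrame  # index exon_id, columns gene_id contig start end
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")


def exon_table(transcripts: list[TranscriptModel]) -> pd.DataFrame:
    rows = []
    for t in transcripts:
        for i, (s, e) in enumerate(t.exons):
            rows.append(
                dict(
                    exon_id=f"{t.gene_id}:e{i}",
                    gene_id=t.gene_id,
                    contig=t.contig,
                    start=s,
                    end=e,
                )
            )
    return pd.DataFrame(rows).set_index("exon_id")


def quantify_exons(
    bam: str | Path,
    annotation: list[TranscriptModel] | pd.DataFrame | str | Path,
) -> tuple[pd.Series, int]:
    """Count reads per exon for one individual's BAM.

    ``annotation`` may be a transcript list, an exon table, or a GTF
    path.  Exons must be non-overlapping (merged beforehand).  Returns
    (counts indexed by exon id, number of uncounted reads).
    """
    if isinstance(annotation, (str, Path)):
        annotation = read_gtf(annotation)
    exons = annotation if isinstance(annotation, pd.DataFrame) else exon_table(annotation)

    by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for contig, sub in exons.groupby("contig"):
        sub = sub.sort_values("start")
        starts, ends = sub.start.to_numpy(), sub.end.to_numpy()
        if (starts[1:] <= ends[:-1]).any():
            raise ValueError("exons must be non-overlapping; merge them first")
        by_contig[contig] = (starts, ends, sub.index.to_numpy())

    counts = pd.Series(0, index=exons.index, dtype=np.int64)
    uncounted = 0
    with pysam.AlignmentFile(str(bam), "rb") as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                uncounted += 1
                continue
            trio = by_contig.get(rec.reference_name)
            if trio is None:
                uncounted += 1
                continue
            starts, ends, ids = trio
            pos = rec.reference_start + 1
            i = np.searchsorted(starts, pos, side="right") - 1
            if i >= 0 and pos <= ends[i]:
                counts[ids[i]] += 1
            else:
                uncounted += 1
    return counts, uncounted


def count_matrix(
    bams: list[str | Path],
    annotation: list[TranscriptModel] | pd.DataFrame,
    sample_ids: list[str] | None = None,
) -> ExonCountMatrix:
    """Quantify a cohort of BAMs into one exons x individuals matrix."""
    exons = annotation if isinstance(annotation, pd.DataFrame) else exon_table(annotation)
    if sample_ids is None:
        sample_ids = [Path(b).stem for b in bams]
    cols = {}
    for sid, bam in zip(sample_ids, bams):
        counts, _ = quantify_exons(bam, exons)
        cols[sid] = counts
    return ExonCountMatrix(counts=pd.DataFrame(cols), exons=exons)


def filter_and_normalize(
    matrix: ExonCountMatrix,
    presence_frac: float = 0.9,
    covariates: pd.DataFrame | None = None,
    scale: float = 1e6,
) -> ExonCountMatrix:
    """Presence-filter exons and normalize by per-individual totals.

    Keeps exons with >0 reads in strictly more than ``presence_frac``
    of individuals.  Each individual's counts are divided by its total
    exon-mapped reads (over all exons, before presence filtering) and
    multiplied by ``scale``.  If covariates are given (individuals x
    covariates), they are regressed out of log2(normalized + 1) by
    least squares and the residuals returned.
    """
    if not (0.0 < presence_frac <= 1.0):
        raise ValueError("presence_frac must be in (0, 1]")
    raw = matrix.counts
    n = raw.shape[1]
    keep = (raw > 0).sum(axis=1) / n > presence_frac
    if not keep.any():
        raise ValueError("presence filter removed every exon")
    totals = raw.sum(axis=0).astype(float)
    norm = raw.loc[keep] / totals * scale
    if covariates is not None:
        X = np.column_stack([np.ones(n), covariates.loc[norm.columns].to_numpy()])
        Y = np.log2(norm.to_numpy() + 1.0)
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        norm = pd.DataFrame(
            (Y.T - X @ beta).T, index=norm.index, columns=norm.columns
        )
    return ExonCountMatrix(
        counts=raw.loc[keep], exons=matrix.exons.loc[keep.index[keep]], normalized=norm
    )
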