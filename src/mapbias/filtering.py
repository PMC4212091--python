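"""Remove RNA-seq reads mapped to biased start sites.

Filtering is genotype-blind by construction: a read is removed iff its
leftmost aligned reference position is in the biased-site set, for
every individual alike.  Under the FRAGMENT pair policy both mates go
if either matches; under the default READ policy mates are judged
independently (the catalog is a start-site list, not a fragment list).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pysam


@dataclass
class BiasedSiteSet:
    """Deduplicated (contig, 1-based leftmost position) pairs."""

    sites: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sites = set(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.sites


@dataclass
class FilterStats:
    n_input: int = 0
    n_removed: int = 0
    n_retained: int = 0
    n_unmapped_retained: int = 0


def filter_alignments(
    in_bam: str | Path,
    sites: BiasedSiteSet | set,
    out_bam: str | Path,
    pair_policy: str = "READ",
) -> FilterStats:
    """Copy a coordinate-sorted BAM, dropping reads at biased starts.

    Unmapped reads are always retained; the output stays coordinate-
    sorted because filtering only deletes records.  Conservation holds
    exactly: n_input = n_removed + n_retained.
    """
    if pair_policy not in ("READ", "FRAGMENT"):
        raise ValueError("pair_policy must be READ or FRAGMENT")
    site_set = sites.sites if isinstance(sites, BiasedSiteSet) else set(sites)
    if not site_set:
        warnings.warn("empty biased-site set: output is an identity copy")

    stats = FilterStats()
    in_bam, out_bam = str(in_bam), str(out_bam)

    with pysam.AlignmentFile(in_bam, "rb") as src:
        so = src.header.to_dict().get("HD", {}).get("SO", "")
        if so != "coordinate":
            raise ValueError("input BAM must be coordinate-sorted")

        def _hit(rec: pysam.AlignedSegment) -> bool:
            return (not rec.is_unmapped) and (
                (rec.reference_name, rec.reference_start + 1) in site_set
            )

        doomed_fragments: set[str] = set()
        if pair_policy == "FRAGMENT":
            for rec in src.fetch(until_eof=True):
                if _hit(rec):
                    doomed_fragments.add(rec.query_name)
            src.reset()

        last = (-1, -1)
        with pysam.AlignmentFile(out_bam, "wb", header=src.header) as dst:
            for rec in src.fetch(until_eof=True):
                stats.n_input += 1
                if not rec.is_unmapped:
                    key = (rec.reference_id, rec.reference_start)
                    if key < last:
                        raise ValueError("input BAM records out of coordinate order")
                    last = key
                remove = (
                    rec.query_name in doomed_fragments
                    if pair_policy == "FRAGMENT"
                    else _hit(rec)
                )
                if remove:
                    stats.n_removed += 1
                else:
                    stats.n_retained += 1
                    if rec.is_unmapped:
                        stats.n_unmapped_retained += 1
                    dst.write(rec)
    return stats
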