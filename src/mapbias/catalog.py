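"""Aggregate per-read correctness into site- and variant-level bias records.

A *site* is a (focal variant, read start) pair; it is biased when reads
from different local haplotypes at that start do not share a single
correctness value.  A *variant* is flagged when the mapping rates of
all its reference reads and all its non-reference reads, pooled over
every start site, differ by more than the bias threshold (default 5%,
strict inequality).  The flag direction is REF when reference reads map
better — the only possible direction for variants with no flanking
variants in any window — and ALT when linkage to a flanking variant
biases mapping the other way (the secondary effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .mapping import AlignmentResult, PairAlignmentResult, judge_correctness, judge_pair_correctness
from .reads import SimRead


@dataclass(frozen=True)
class BiasConfig:
    bias_threshold: float = 0.05  # strict: flagged iff |delta| > threshold

    def __post_init__(self) -> None:
        if not (0.0 < self.bias_threshold < 1.0):
            raise ValueError("bias_threshold must be in (0, 1)")


@dataclass(frozen=True)
class JudgedRead:
    """The bias-relevant facts about one simulated, mapped, judged read."""

    focal_variant: str
    vclass: str
    contig: str
    origin_start: int
    hap_signature: str
    focal_allele: str
    correct: bool


@dataclass(frozen=True)
class SiteBiasRecord:
    contig: str
    start: int
    focal_variant: str
    haplotype_correct: tuple[tuple[str, bool], ...]
    biased: bool


def judge_reads(
    mapped: Iterable[tuple[SimRead, AlignmentResult | PairAlignmentResult]],
    vclass_of: dict[str, str],
    pos_tolerance: int = 0,
) -> list[JudgedRead]:
    """Apply the correctness policy to a mapped-read stream."""
    out = []
    for sim, aln in mapped:
        if isinstance(aln, PairAlignmentResult):
            ok = judge_pair_correctness(sim, aln, pos_tolerance)
        else:
            ok = judge_correctness(sim, aln, pos_tolerance)
        out.append(
            JudgedRead(
                focal_variant=sim.focal_variant,
                vclass=vclass_of.get(sim.focal_variant, "SNP"),
                contig=sim.origin_contig,
                origin_start=sim.origin_start,
                hap_signature=sim.hap_signature,
                focal_allele=sim.focal_allele,
                correct=ok,
            )
        )
    return out


def summarize_site_bias(judged: Iterable[JudgedRead]) -> list[SiteBiasRecord]:
    """One record per (focal variant, start site).

    A site is biased iff its haplotype classes do not all share one
    correctness value.
    """
    groups: dict[tuple[str, str, int], list[JudgedRead]] = {}
    for r in judged:
        groups.setdefault((r.focal_variant, r.contig, r.origin_start), []).append(r)
    records = []
    for (vid, contig, start), rs in sorted(groups.items()):
        flags = tuple((r.hap_signature, r.correct) for r in rs)
        biased = len({r.correct for r in rs}) > 1
        records.append(SiteBiasRecord(contig, start, vid, flags, biased))
    return records


def biased_site_set(site_records: Iterable[SiteBiasRecord]) -> set[tuple[str, int]]:
    """Deduplicated union of biased (contig, start) sites over variants."""
    return {(r.contig, r.start) for r in site_records if r.biased}


def summarize_variant_bias(
    judged: Iterable[JudgedRead],
    cfg: BiasConfig = BiasConfig(),
) -> pd.DataFrame:
    """Per-variant pooled mapping rates and bias flags.

    Columns: variant, vclass, n_ref_reads, n_alt_reads, n_ref_correct,
    n_alt_correct, rate_ref, rate_alt, delta (rate_ref - rate_alt),
    ref_ratio (NaN when no read of either allele maps), flagged,
    direction (REF | ALT | NONE).
    """
    df = pd.DataFrame([r.__dict__ for r in judged])
    if df.empty:
        raise ValueError("no judged reads")
    rows = []
    for vid, sub in df.groupby("focal_variant", sort=True):
        ref = sub[sub.focal_allele == "R"]
        alt = sub[sub.focal_allele == "A"]
        if len(ref) == 0 or len(alt) == 0:
            raise ValueError(f"variant {vid} lacks simulated reads for one allele")
        n_ref_c, n_alt_c = int(ref.correct.sum()), int(alt.correct.sum())
        rate_ref = n_ref_c / len(ref)
        rate_alt = n_alt_c / len(alt)
        delta = rate_ref - rate_alt
        flagged = abs(delta) > cfg.bias_threshold
        direction = "NONE" if not flagged else ("REF" if delta > 0 else "ALT")
        rows.append(
            dict(
                variant=vid,
                vclass=sub.vclass.iloc[0],
                n_ref_reads=len(ref),
                n_alt_reads=len(alt),
                n_ref_correct=n_ref_c,
                n_alt_correct=n_alt_c,
                rate_ref=rate_ref,
                rate_alt=rate_alt,
                delta=delta,
                ref_ratio=(n_ref_c / (n_ref_c + n_alt_c)) if (n_ref_c + n_alt_c) else math.nan,
                flagged=flagged,
                direction=direction,
            )
        )
    return pd.DataFrame(rows)


def compare_catalogs(cat_a: pd.DataFrame, cat_b: pd.DataFrame) -> dict:
    """Concordance of two variant catalogs (e.g. two simulation modes).

    Spearman rank correlation of ref_ratio over shared variants,
    overall and stratified by variant class; percent flagged in each
    catalog; and the fraction of catalog A's flagged set that is also
    flagged in B.
    """
    merged = cat_a.merge(cat_b, on="variant", suffixes=("_a", "_b"))
    shared = merged.dropna(subset=["ref_ratio_a", "ref_ratio_b"])
    if len(shared) < 2:
        raise ValueError("need >= 2 shared variants with defined ref_ratio")

    def _rho(sub: pd.DataFrame) -> float:
        if len(sub) < 2 or sub.ref_ratio_a.nunique() < 2 or sub.ref_ratio_b.nunique() < 2:
            return math.nan
        return float(stats.spearmanr(sub.ref_ratio_a, sub.ref_ratio_b).statistic)

    by_class = {
        cls: _rho(sub) for cls, sub in shared.groupby("vclass_a")
    }
    flagged_a = set(merged.loc[merged.flagged_a, "variant"])
    flagged_b = set(merged.loc[merged.flagged_b, "variant"])
    return dict(
        n_shared=len(shared),
        rho_overall=_rho(shared),
        rho_by_class=by_class,
        pct_flagged_a=100.0 * cat_a.flagged.mean(),
        pct_flagged_b=100.0 * cat_b.flagged.mean(),
        pct_a_flagged_also_in_b=(
            100.0 * len(flagged_a & flagged_b) / len(flagged_a) if flagged_a else math.nan
        ),
    )


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def write_variant_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_variant_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_biased_sites_bed(sites: set[tuple[str, int]], path: str | Path) -> None:
    """Single-base BED intervals (0-based half-open) of biased starts."""
    with open(path, "w") as fh:
        for contig, pos in sorted(sites):
            fh.write(f"{contig}\t{pos - 1}\t{pos}\n")


def read_biased_sites_bed(path: str | Path) -> set[tuple[str, int]]:
    sites = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start0, _end = line.split()[:3]
            sites.add((contig, int(start0) + 1))
    return sites
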