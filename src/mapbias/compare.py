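"""Before/after-filtering eQTL comparison and bias enrichment tests.

Genes are classified COMMON / LOST / GAINED / NEVER according to
whether they are significant in both, only the unfiltered, only the
filtered, or neither analysis (both called at the identical empirical-P
threshold).  Lost associations whose nominal log10 P worsens by more
than a drop threshold are flagged as likely false positives driven by
mapping bias.  Two enrichment tests ask whether eQTL signals track the
simulated bias catalog: a Fisher exact test on exon-variant overlap by
class, and a TSS-distance-matched comparison of the simulated bias of
eQTL variants against a matched random null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import HaplotypePanel, VariantRecord


@dataclass
class EqtlComparison:
    """Per-gene before/after table plus summary counts."""

    table: pd.DataFrame  # gene, p_before, p_after, class, dlogp, large_drop
    counts: dict = field(default_factory=dict)


@dataclass
class EnrichmentReport:
    contingency: np.ndarray | None = None
    fisher_p: float | None = None
    mannwhitney_p: float | None = None
    proportions: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


P_FLOOR = 1e-300  # keeps log10 finite for underflowing nominal P


def classify_eqtl_changes(
    results_before: pd.DataFrame,
    results_after: pd.DataFrame,
    sig_before: set[str],
    sig_after: set[str],
    drop_threshold: float = 20.0,
) -> EqtlComparison:
    """Classify each gene by significance before vs after filtering.

    ``results_*`` are gene-level tables from the eQTL scan (columns
    gene, p_nominal, p_empirical); both analyses must have been called
    at the identical threshold.  dlogp = log10 p_before - log10
    p_after on the gene-best nominal P; genes untested after filtering
    (their only informative exon disappeared) take p_after = 1.
    large_drop marks LOST genes whose log10 P worsened by more than
    ``drop_threshold``.
    """
    before = results_before.set_index("gene")
    after = results_after.set_index("gene")
    genes = before.index.union(after.index)
    if not len(before.index.intersection(after.index)):
        raise ValueError("gene sets are disjoint; mismatched inputs?")
    rows = []
    for g in genes:
        pb = before.p_nominal.get(g, np.nan)
        pa = after.p_nominal.get(g, np.nan)
        pb_ = 1.0 if np.isnan(pb) else max(pb, P_FLOOR)
        pa_ = 1.0 if np.isnan(pa) else max(pa, P_FLOOR)
        sb, sa = g in sig_before, g in sig_after
        cls = {(True, True): "COMMON", (True, False): "LOST",
               (False, True): "GAINED", (False, False): "NEVER"}[(sb, sa)]
        dlogp = np.log10(pb_) - np.log10(pa_)
        rows.append(
            dict(
                gene=g, p_before=pb, p_after=pa, **{"class": cls},
                dlogp=dlogp,
                large_drop=(cls == "LOST" and abs(dlogp) > drop_threshold),
            )
        )
    table = pd.DataFrame(rows)
    counts = table["class"].value_counts().to_dict()
    for k in ("COMMON", "LOST", "GAINED", "NEVER"):
        counts.setdefault(k, 0)
    return EqtlComparison(table=table, counts=counts)


def _has_variant(interval: tuple[str, int, int], variants: list[VariantRecord]) -> bool:
    contig, s, e = interval
    return any(v.contig == contig and v.pos <= e and v.end >= s for v in variants)


def variant_overlap_enrichment(
    exons_by_class: dict[str, list[tuple[str, int, int]]],
    panel: HaplotypePanel,
    class_a: str = "LOST",
    class_b: str = "GAINED",
) -> EnrichmentReport:
    """Do best-associated exons of one class contain variants more often?

    Builds, per class, the proportion of exons containing at least one
    panel variant, and tests class_a vs class_b with a two-sided Fisher
    exact test on the 2x2 (class x has-variant) table.
    """
    report = EnrichmentReport()
    for cls, exons in exons_by_class.items():
        if not exons:
            raise ValueError(f"class {cls} has no exons")
        hits = sum(_has_variant(e, panel.variants) for e in exons)
        report.proportions[cls] = hits / len(exons)
    tab = []
    for cls in (class_a, class_b):
        exons = exons_by_class[cls]
        hits = sum(_has_variant(e, panel.variants) for e in exons)
        tab.append([hits, len(exons) - hits])
    table = np.array(tab)
    report.contingency = table
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        report.fisher_p = 1.0
        report.warnings.append("degenerate contingency table (zero margin)")
        warnings.warn(report.warnings[-1])
    else:
        report.fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return report


def tss_matched_bias_enrichment(
    eqtl_variants: list[str],
    tss_distance: dict[str, int],
    catalog: pd.DataFrame,
    candidate_variants: list[str] | None = None,
    n_bins: int = 10,
    seed: int = 0,
    bias_threshold: float = 0.05,
) -> EnrichmentReport:
    """Is the simulated bias of eQTL variants above its matched null?

    The eQTL variants are binned by |distance to their gene's TSS|
    into ``n_bins`` equal-occupancy bins, and an equal-size null set is
    sampled from ``candidate_variants`` (default: every catalog
    variant) matching the bin histogram, without replacement when the
    bin has enough candidates (with replacement plus a warning
    otherwise).  Flagged proportions (|delta| > bias_threshold) are
    compared by a two-sided Fisher exact test and the full |delta|
    distributions by a two-sided Mann-Whitney test.
    """
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    cat = catalog.set_index("variant")
    rng = np.random.default_rng(seed)
    report = EnrichmentReport()

    eq = [v for v in eqtl_variants if v in cat.index and v in tss_distance]
    if candidate_variants is None:
        candidate_variants = [v for v in cat.index if v in tss_distance]
    d_eq = np.abs([tss_distance[v] for v in eq])
    edges = np.quantile(d_eq, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    eq_bins = np.searchsorted(edges, d_eq, side="left") - 1
    cand = np.array(candidate_variants)
    d_cand = np.abs([tss_distance[v] for v in cand])
    cand_bins = np.searchsorted(edges, d_cand, side="left") - 1

    null: list[str] = []
    for b in range(n_bins):
        need = int((eq_bins == b).sum())
        pool = cand[cand_bins == b]
        if need == 0:
            continue
        if len(pool) >= need:
            null.extend(rng.choice(pool, size=need, replace=False))
        else:
            report.warnings.append(f"bin {b}: resampled with replacement")
            warnings.warn(report.warnings[-1])
            null.extend(rng.choice(pool, size=need, replace=True))

    d_eq_abs = cat.loc[eq, "delta"].abs().to_numpy()
    d_null_abs = cat.loc[null, "delta"].abs().to_numpy()
    flag_eq = int((d_eq_abs > bias_threshold).sum())
    flag_null = int((d_null_abs > bias_threshold).sum())
    table = np.array(
        [[flag_eq, len(eq) - flag_eq], [flag_null, len(null) - flag_null]]
    )
    report.contingency = table
    report.proportions = {
        "eqtl_flagged": flag_eq / len(eq) if eq else np.nan,
        "null_flagged": flag_null / len(null) if null else np.nan,
    }
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        report.fisher_p = 1.0
        report.warnings.append("degenerate contingency table (zero margin)")
    else:
        report.fisher_p = float(stats.fisher_exact(table)[1])
    if np.array_equal(np.sort(d_eq_abs), np.sort(d_null_abs)):
        report.mannwhitney_p = 1.0  # identical distributions
    else:
        report.mannwhitney_p = float(
            stats.mannwhitneyu(d_eq_abs, d_null_abs, alternative="two-sided").pvalue
        )
    return report
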