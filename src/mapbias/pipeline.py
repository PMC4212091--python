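"""End-to-end orchestration of the mapping-bias analysis.

``catalog_from_panel`` runs simulation -> mapping -> judgment ->
catalog for one panel and mode; ``run_cohort_analysis`` runs the full
study on a synthetic cohort: build the biased-site catalog, simulate
and align the RNA-seq cohort, quantify exons, map cis-eQTLs, filter
reads at biased start sites, re-quantify, re-map under the identical
significance threshold, and classify genes as common / lost / gained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalog import (
    BiasConfig,
    JudgedRead,
    biased_site_set,
    judge_reads,
    summarize_site_bias,
    summarize_variant_bias,
)
from .compare import EqtlComparison, classify_eqtl_changes
from .eqtl import EqtlConfig, call_eqtl_genes, map_cohort_eqtls
from .filtering import BiasedSiteSet, filter_alignments
from .mapping import BuiltinMapper, map_reads
from .quantify import ExonCountMatrix, count_matrix, filter_and_normalize
from .reads import build_simulated_reads
from .synthetic import CohortFixture, HaplotypePanel, SimulationConfig, simulate_rnaseq_cohort


def catalog_from_panel(
    reference: dict[str, str],
    panel: HaplotypePanel,
    config: SimulationConfig,
    mode: str = "GENOME_SE",
    bias_cfg: BiasConfig = BiasConfig(),
    mapper: BuiltinMapper | None = None,
    transcripts=None,
    pos_tolerance: int = 0,
):
    """Simulate, map and judge all reads; return (judged, sites, catalog).

    ``sites`` is the deduplicated biased (contig, start) set and
    ``catalog`` the per-variant bias table.
    """
    if mapper is None:
        mapper = BuiltinMapper(reference)
    reads, _ = build_simulated_reads(panel, reference, config, mode=mode, transcripts=transcripts)
    vclass = {v.vid: v.vclass for v in panel.variants}
    judged = judge_reads(
        map_reads(reads, mapper, inner_insert=config.inner_insert),
        vclass,
        pos_tolerance=pos_tolerance,
    )
    site_records = summarize_site_bias(judged)
    sites = biased_site_set(site_records)
    cat = summarize_variant_bias(judged, bias_cfg)
    return judged, sites, cat


@dataclass
class CohortAnalysis:
    """Everything the before/after comparison produces."""

    sites: set
    variant_catalog: pd.DataFrame
    matrix_before: ExonCountMatrix
    matrix_after: ExonCountMatrix
    results_before: pd.DataFrame
    results_after: pd.DataFrame
    sig_before: set
    sig_after: set
    threshold: float | None
    comparison: EqtlComparison
    filter_stats: list
    depth: pd.DataFrame


def run_cohort_analysis(
    fixture: CohortFixture,
    workdir: str | Path,
    eqtl_cfg: EqtlConfig | None = None,
    bias_cfg: BiasConfig = BiasConfig(),
    presence_frac: float = 0.9,
    drop_threshold: float = 20.0,
    cohort_seed: int | None = None,
) -> CohortAnalysis:
    workdir = Path(workdir)
    cfg = fixture.config
    if eqtl_cfg is None:
        eqtl_cfg = EqtlConfig(rng_seed=cfg.rng_seed)
    mapper = BuiltinMapper(fixture.reference)

    _, sites, cat = catalog_from_panel(
        fixture.reference, fixture.panel, cfg, mode="GENOME_SE",
        bias_cfg=bias_cfg, mapper=mapper,
    )

    bams, depth = simulate_rnaseq_cohort(
        fixture, workdir / "cohort", mapper=mapper, rng_seed=cohort_seed
    )

    matrix_before = filter_and_normalize(
        count_matrix(bams, fixture.transcripts, fixture.panel.sample_ids),
        presence_frac=presence_frac,
    )
    results_before = map_cohort_eqtls(
        matrix_before, fixture.panel, fixture.transcripts, eqtl_cfg
    )
    sig_before, threshold = call_eqtl_genes(results_before, eqtl_cfg)

    site_set = BiasedSiteSet(sites)
    filtered_dir = workdir / "filtered"
    filtered_dir.mkdir(parents=True, exist_ok=True)
    stats_list = []
    filtered_bams = []
    for bam in bams:
        out = filtered_dir / Path(bam).name
        stats_list.append(filter_alignments(bam, site_set, out))
        filtered_bams.append(out)

    matrix_after = filter_and_normalize(
        count_matrix(filtered_bams, fixture.transcripts, fixture.panel.sample_ids),
        presence_frac=presence_frac,
    )
    results_after = map_cohort_eqtls(
        matrix_after, fixture.panel, fixture.transcripts, eqtl_cfg
    )
    if threshold is None:
        sig_after: set = set()
    else:
        sig_after, _ = call_eqtl_genes(results_after, eqtl_cfg, p_threshold=threshold)

    comparison = classify_eqtl_changes(
        results_before, results_after, sig_before, sig_after, drop_threshold=drop_threshold
    )
    return CohortAnalysis(
        sites=sites,
        variant_catalog=cat,
        matrix_before=matrix_before,
        matrix_after=matrix_after,
        results_before=results_before,
        results_after=results_after,
        sig_before=sig_before,
        sig_after=sig_after,
        threshold=threshold,
        comparison=comparison,
        filter_stats=stats_list,
        depth=depth,
    )
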