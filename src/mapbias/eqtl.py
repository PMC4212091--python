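"""cis-eQTL mapping by Spearman rank correlation with permutation FDR.

For every gene, every (quantified exon, cis variant) pair is tested by
Spearman rank correlation between normalized expression and alt-allele
dosage (0/1/2, midrank ties).  The gene-level statistic is the minimum
nominal P over its pairs; its empirical P comes from permuting
individual labels of the expression matrix (the same permutation order
for every gene within a run) and recomputing the gene best each time,
with the add-one estimator p = (1 + #{perm best <= observed}) /
(n_perm + 1).  Gene-level significance is Benjamini-Hochberg on the
empirical P values at the target FDR; the realized empirical-P
threshold is recorded so a re-analysis of filtered data can reuse the
identical threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import ExonCountMatrix
from .synthetic import HaplotypePanel, TranscriptModel


@dataclass(frozen=True)
class EqtlConfig:
    cis_window: int = 1_000_000  # bases either side of the TSS
    n_perm: int = 1000
    fdr: float = 0.10
    rng_seed: int = 0
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must be in (0, 1)")


@dataclass(frozen=True)
class AssociationResult:
    gene: str
    exon: str
    variant: str
    rho: float
    p_nominal: float
    p_empirical: float | None = None
    significant: bool | None = None


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Midrank-transform each row, then center and scale to unit norm."""
    r = stats.rankdata(x, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norms = np.sqrt((r ** 2).sum(axis=1))
    norms[norms == 0] = np.inf  # constant rows correlate with nothing
    return r / norms[:, None]


def spearman_rho(expr: np.ndarray, geno: np.ndarray) -> np.ndarray:
    """Spearman rho matrix between rows of expr and rows of geno."""
    return _rank_rows(np.asarray(expr, float)) @ _rank_rows(np.asarray(geno, float)).T


def _nominal_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-approximation P for Spearman rho at sample size n."""
    rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def cis_variants(
    gene: TranscriptModel,
    panel: HaplotypePanel,
    dosages: pd.DataFrame,
    cfg: EqtlConfig,
) -> list[str]:
    """Variants in the cis window around the TSS that are polymorphic
    and above the MAF floor in the sample."""
    out = []
    n2 = 2 * dosages.shape[1]
    for v in panel.variants:
        if v.contig != gene.contig or abs(v.pos - gene.tss) > cfg.cis_window:
            continue
        d = dosages.loc[v.vid].to_numpy()
        af = d.sum() / n2
        maf = min(af, 1 - af)
        if maf <= 0 or maf < cfg.maf_min:
            continue  # monomorphic or too rare in this sample
        out.append(v.vid)
    return out


def cis_associations(
    gene: TranscriptModel,
    expr: pd.DataFrame,
    dosages: pd.DataFrame,
    variant_ids: list[str],
    cfg: EqtlConfig,
) -> tuple[AssociationResult | None, list[AssociationResult], np.ndarray]:
    """All (exon, cis-variant) Spearman tests for one gene.

    ``expr`` holds the gene's quantified exons (rows, ordered by exon
    start) over individuals; ``variant_ids`` the testable cis variants
    (ordered by position).  Returns (gene best, per-exon bests, the
    rho matrix).  Ties in the minimum are broken deterministically by
    (variant position order, exon order).
    """
    if expr.empty or not variant_ids:
        return None, [], np.empty((0, 0))
    G = dosages.loc[variant_ids, expr.columns].to_numpy(float)
    rho = spearman_rho(expr.to_numpy(float), G)
    p = _nominal_p(rho, expr.shape[1])
    exon_best = []
    for i, exon in enumerate(expr.index):
        j = int(np.argmin(p[i]))  # first minimum = smallest variant position
        exon_best.append(
            AssociationResult(gene.gene_id, exon, variant_ids[j], float(rho[i, j]), float(p[i, j]))
        )
    flat = int(np.argmin(p.T))  # variant-major: variant order breaks ties first
    j, i = divmod(flat, p.shape[0])
    best = AssociationResult(
        gene.gene_id, expr.index[i], variant_ids[j], float(rho[i, j]), float(p[i, j])
    )
    return best, exon_best, rho


def gene_permutation_pvalue(
    observed_p: float,
    expr: pd.DataFrame,
    dosages: pd.DataFrame,
    variant_ids: list[str],
    perms: np.ndarray,
) -> float:
    """Empirical P for a gene's best statistic under label permutation.

    ``perms`` is an (n_perm, n_individuals) matrix of permuted column
    indices, shared across genes within a run.
    """
    n = expr.shape[1]
    E = _rank_rows(expr.to_numpy(float))
    G = _rank_rows(dosages.loc[variant_ids, expr.columns].to_numpy(float))
    best_rho = np.array([np.abs(E[:, pi] @ G.T).max() for pi in perms])
    perm_p = _nominal_p(best_rho, n)
    return float((1 + (perm_p <= observed_p).sum()) / (len(perms) + 1))


def permutation_matrix(n: int, n_perm: int, rng_seed: int) -> np.ndarray:
    rng = np.random.default_rng(rng_seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def map_cohort_eqtls(
    matrix: ExonCountMatrix,
    panel: HaplotypePanel,
    transcripts: list[TranscriptModel],
    cfg: EqtlConfig,
    dosages: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene-level cis-eQTL scan over a quantified cohort.

    Returns one row per tested gene: gene, exon, variant, rho,
    p_nominal (gene best) and p_empirical.  Genes with no quantified
    exon or no testable cis variant are reported untested (NaN P).
    """
    expr_all = matrix.normalized if matrix.normalized is not None else matrix.counts
    if dosages is None:
        dosages = panel.dosages()
    dosages = dosages[expr_all.columns]
    perms = permutation_matrix(expr_all.shape[1], cfg.n_perm, cfg.rng_seed)
    exon_gene = matrix.exons.loc[expr_all.index, "gene_id"]
    rows = []
    for gene in transcripts:
        exon_ids = exon_gene.index[exon_gene == gene.gene_id]
        sub = expr_all.loc[exon_ids]
        vids = cis_variants(gene, panel, dosages, cfg)
        best, _, _ = cis_associations(gene, sub, dosages, vids, cfg)
        if best is None:
            rows.append(
                dict(gene=gene.gene_id, exon="", variant="", rho=np.nan,
                     p_nominal=np.nan, p_empirical=np.nan)
            )
            continue
        p_emp = gene_permutation_pvalue(best.p_nominal, sub, dosages, vids, perms)
        rows.append(
            dict(gene=best.gene, exon=best.exon, variant=best.variant,
                 rho=best.rho, p_nominal=best.p_nominal, p_empirical=p_emp)
        )
    return pd.DataFrame(rows)


def call_eqtl_genes(
    results: pd.DataFrame,
    cfg: EqtlConfig,
    p_threshold: float | None = None,
) -> tuple[set[str], float | None]:
    """Significant gene set at the target FDR.

    Benjamini-Hochberg on gene-level empirical P values; returns the
    set and the realized empirical-P threshold (the largest rejected
    P, or None when nothing is rejected).  Passing ``p_threshold``
    skips BH and reuses a previously realized threshold verbatim, as
    when re-analyzing filtered data under the original threshold.
    """
    tested = results.dropna(subset=["p_empirical"])
    if tested.empty:
        raise ValueError("no tested genes")
    p = tested.p_empirical.to_numpy()
    if p_threshold is not None:
        sig = tested.gene[p <= p_threshold]
        return set(sig), p_threshold
    reject, *_ = multipletests(p, alpha=cfg.fdr, method="fdr_bh")
    if not reject.any():
        return set(), None
    threshold = float(p[reject].max())
    return set(tested.gene[reject]), threshold
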