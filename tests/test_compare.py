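"""Before/after classification and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mapbias as mb
from mapbias.compare import (
    classify_eqtl_changes,
    tss_matched_bias_enrichment,
    variant_overlap_enrichment,
)
from mapbias.synthetic import HaplotypePanel, VariantRecord

from oracles import fisher_two_sided, mannwhitney_p_normal, mannwhitney_u


def _results(genes, ps):
    return pd.DataFrame(dict(gene=genes, p_nominal=ps, p_empirical=ps))


def test_classification_matrix():
    before = _results(["a", "b", "c", "d"], [1e-8, 1e-8, 0.5, 0.5])
    after = _results(["a", "b", "c", "d"], [1e-8, 0.5, 1e-8, 0.5])
    cmp_ = classify_eqtl_changes(before, after, {"a", "b"}, {"a", "c"})
    cls = cmp_.table.set_index("gene")["class"].to_dict()
    assert cls == {"a": "COMMON", "b": "LOST", "c": "GAINED", "d": "NEVER"}
    assert sum(cmp_.counts.values()) == 4  # classes partition the gene set


def test_identity_comparison_has_no_changes():
    res = _results(list("abcde"), [1e-9, 1e-6, 0.01, 0.2, 0.9])
    cmp_ = classify_eqtl_changes(res, res, {"a", "b"}, {"a", "b"})
    assert cmp_.counts["LOST"] == cmp_.counts["GAINED"] == 0
    assert (cmp_.table.dlogp == 0).all()
    assert not cmp_.table.large_drop.any()


def test_large_drop_flag():
    before = _results(["a"], [1e-30])
    after = _results(["a"], [0.5])
    cmp_ = classify_eqtl_changes(before, after, {"a"}, set(), drop_threshold=20)
    assert cmp_.table.large_drop.iloc[0]
    assert cmp_.table.dlogp.iloc[0] == pytest.approx(np.log10(1e-30) - np.log10(0.5))


def test_untested_after_takes_p_one():
    before = _results(["a"], [1e-10])
    after = _results(["a"], [np.nan])
    cmp_ = classify_eqtl_changes(before, after, {"a"}, set(), drop_threshold=5)
    assert cmp_.table.large_drop.iloc[0]


def test_disjoint_gene_sets_rejected():
    with pytest.raises(ValueError):
        classify_eqtl_changes(_results(["a"], [0.5]), _results(["b"], [0.5]), set(), set())


def _panel_with(positions):
    variants = [VariantRecord(f"v{i}", "chr1", p, "A", "C", 0.3) for i, p in enumerate(positions)]
    haps = np.zeros((4, len(variants)), dtype=np.int8)
    haps[0] = 1
    return HaplotypePanel(variants, haps, ["s0", "s1"])


def test_variant_overlap_enrichment_against_exact_oracle():
    panel = _panel_with([1050, 3050])
    lost = [("chr1", 1000, 1100)] * 8 + [("chr1", 5000, 5100)] * 2
    gained = [("chr1", 1000, 1100)] * 2 + [("chr1", 5000, 5100)] * 8
    rep = variant_overlap_enrichment({"LOST": lost, "GAINED": gained}, panel)
    assert rep.proportions["LOST"] == pytest.approx(0.8)
    assert rep.contingency.tolist() == [[8, 2], [2, 8]]
    assert rep.fisher_p == pytest.approx(fisher_two_sided([[8, 2], [2, 8]]), rel=1e-6)
    assert rep.fisher_p == pytest.approx(0.023, abs=0.002)


def test_identical_proportions_give_p_one():
    panel = _panel_with([1050])
    ex = [("chr1", 1000, 1100)] * 5 + [("chr1", 9000, 9100)] * 5
    rep = variant_overlap_enrichment({"LOST": ex, "GAINED": list(ex)}, panel)
    assert rep.fisher_p == pytest.approx(1.0)


def test_degenerate_table_warns_and_reports_one():
    panel = _panel_with([1050])
    with_v = [("chr1", 1000, 1100)] * 4
    with pytest.warns(UserWarning):
        rep = variant_overlap_enrichment({"LOST": with_v, "GAINED": list(with_v)}, panel)
    assert rep.fisher_p == 1.0


def _catalog(vids, deltas):
    return pd.DataFrame(dict(variant=vids, vclass="SNP", delta=deltas,
                             flagged=[abs(d) > 0.05 for d in deltas]))


def test_tss_matched_identity_null():
    vids = [f"v{i}" for i in range(50)]
    cat = _catalog(vids, np.linspace(0, 0.4, 50))
    dist = {v: 100 * i for i, v in enumerate(vids)}
    rep = tss_matched_bias_enrichment(vids, dist, cat, candidate_variants=vids, n_bins=5, seed=0)
    assert rep.fisher_p == pytest.approx(1.0)
    assert rep.mannwhitney_p == pytest.approx(1.0)


def test_matched_sample_reproduces_tss_histogram():
    rng = np.random.default_rng(3)
    vids = [f"v{i}" for i in range(400)]
    cat = _catalog(vids, rng.uniform(0, 0.2, 400))
    dist = {v: int(rng.integers(0, 100_000)) for v in vids}
    eq = vids[:80]
    rep = tss_matched_bias_enrichment(eq, dist, cat, candidate_variants=vids, n_bins=8, seed=1)
    # bins were matched by construction: contingency rows have equal size
    assert rep.contingency.sum(axis=1).tolist() == [80, 80]


def test_extreme_enrichment_detected():
    vids = [f"v{i}" for i in range(300)]
    deltas = [0.5] * 40 + [0.0] * 260  # the 40 eQTL variants are all biased
    cat = _catalog(vids, deltas)
    dist = {v: 1000 for v in vids}
    rep = tss_matched_bias_enrichment(vids[:40], dist, cat, candidate_variants=vids[40:], n_bins=5, seed=2)
    assert rep.fisher_p < 0.01


def test_mannwhitney_brute_force_agreement(rng):
    x = rng.integers(0, 10, size=30).astype(float)
    y = rng.integers(0, 10, size=25).astype(float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.statistic == pytest.approx(mannwhitney_u(x, y))
    assert res.pvalue == pytest.approx(mannwhitney_p_normal(x, y), rel=1e-6)


def test_cohort_lost_genes_are_planted_bias_genes(cohort_fixture, cohort_analysis):
    truth = cohort_fixture.truth.genes.set_index("gene_id")
    tbl = cohort_analysis.comparison.table.set_index("gene")
    bias_genes = truth[truth.effect_class == "BIAS_FALSE_EQTL"].index
    assert (tbl.loc[bias_genes, "class"] == "LOST").sum() >= 4
    # lost-class exons are enriched for exonic variants by construction
    res_b = cohort_analysis.results_before.set_index("gene")
    exon_meta = cohort_analysis.matrix_before.exons
    by_class = {}
    for cls in ("LOST", "COMMON"):
        genes = tbl[tbl["class"] == cls].index
        exons = []
        for g in genes:
            if g in res_b.index and res_b.loc[g, "exon"] in exon_meta.index:
                e = exon_meta.loc[res_b.loc[g, "exon"]]
                exons.append((e.contig, int(e.start), int(e.end)))
        by_class[cls] = exons
    rep = variant_overlap_enrichment(by_class, cohort_fixture.panel, "LOST", "COMMON")
    assert rep.proportions["LOST"] >= rep.proportions["COMMON"]
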