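"""Enrichment statistics: running-sum ES, preranked GSEA, ssGSEA."""

import numpy as np
import pandas as pd
import pytest

from tme_profiler.cohort_io import ExpressionMatrix, GeneSet, ValidationError
from tme_profiler.datasets import toy_metabolic_sets
from tme_profiler.enrichment import es, preranked_gsea, rank_genes, ssgsea


def ranked(n=10, seed=0):
    rng = np.random.default_rng(seed)
    metric = pd.Series(np.sort(rng.normal(size=n))[::-1], index=[f"g{i}" for i in range(n)])
    return metric


def brute_force_es(order, members, metric, alpha):
    """Independent running-sum enumeration (plain Python loop)."""
    n = len(order)
    nr = sum(abs(metric[g]) ** alpha for g in order if g in members)
    k = sum(1 for g in order if g in members)
    running, best = 0.0, 0.0
    for g in order:
        if g in members:
            running += abs(metric[g]) ** alpha / nr
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def test_singleton_first_and_last_positions():
    r = ranked(10)
    assert es(r, GeneSet("s", frozenset({"g0"})), alpha=0.0) == pytest.approx(1.0)
    assert es(r, GeneSet("s", frozenset({"g9"})), alpha=0.0) == pytest.approx(-1.0)


def test_es_matches_brute_force_all_singletons():
    """ES equals an independent running-sum enumeration for every singleton
    position on small universes."""
    for n in (3, 5, 12):
        r = ranked(n, seed=n)
        for i in range(n):
            gs = GeneSet("s", frozenset({f"g{i}"}))
            expected = brute_force_es(list(r.index), gs.genes, r, 0.0)
            assert es(r, gs, alpha=0.0) == pytest.approx(expected, abs=1e-12)


def test_es_matches_brute_force_random_sets():
    rng = np.random.default_rng(9)
    r = ranked(12, seed=2)
    for _ in range(20):
        k = rng.integers(1, 6)
        members = frozenset(rng.choice(r.index, size=k, replace=False))
        for alpha in (0.0, 1.0):
            expected = brute_force_es(list(r.index), members, r, alpha)
            assert es(r, GeneSet("s", members), alpha=alpha) == pytest.approx(
                expected, abs=1e-12
            )


def test_es_bounded_and_rank_only_for_alpha_zero():
    r = ranked(30, seed=5)
    gs = GeneSet("s", frozenset({"g2", "g7", "g20"}))
    val = es(r, gs, alpha=0.0)
    assert -1.0 - 1e-9 <= val <= 1.0 + 1e-9
    # strictly monotone transform of the metric leaves alpha=0 ES unchanged
    transformed = pd.Series(np.exp(r.to_numpy() / 2), index=r.index)
    assert es(transformed, gs, alpha=0.0) == pytest.approx(val, abs=1e-12)


def test_es_against_gseapy_oracle():
    """Cross-check the weighted (alpha=1) ES against an independent GSEA
    implementation."""
    gseapy = pytest.importorskip("gseapy")
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(50)]
    metric = pd.Series(rng.normal(size=50), index=genes).sort_values(ascending=False)
    members = [f"g{i}" for i in range(0, 50, 7)]
    rnk = metric.reset_index()
    rnk.columns = ["gene", "score"]
    res = gseapy.prerank(rnk=rnk, gene_sets={"S1": members}, permutation_num=10,
                         seed=1, min_size=2, max_size=500, weight=1.0,
                         outdir=None, no_plot=True)
    theirs = float(res.res2d["ES"].iloc[0])
    ours = es(metric, GeneSet("S1", frozenset(members)), alpha=1.0)
    assert ours == pytest.approx(theirs, abs=1e-9)


def test_set_covering_universe_rejected():
    r = ranked(4)
    with pytest.raises(ValidationError):
        es(r, GeneSet("all", frozenset(r.index)), alpha=0.0)


def test_preranked_planted_set_enriched_and_deterministic():
    rng = np.random.default_rng(3)
    n = 200
    metric = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
    top = metric.sort_values(ascending=False).index[:15]
    planted = GeneSet("planted", frozenset(top))
    decoy = GeneSet("decoy", frozenset(rng.choice(metric.index, 15, replace=False)))
    res1 = preranked_gsea(metric, [planted, decoy], nperm=1000, seed=7)
    res2 = preranked_gsea(metric, [planted, decoy], nperm=1000, seed=7)
    pd.testing.assert_frame_equal(res1, res2)
    row = res1.set_index("name").loc["planted"]
    assert row["nes"] > 0 and row["p"] < 0.05
    assert np.sign(row["nes"]) == np.sign(row["es"])


def test_preranked_null_pvalues_superuniform():
    """Under no signal, preranked p-values stay close to U[0,1].

    Pools 50 sets over 5 independent null rankings: the Kolmogorov bound of
    0.1 is only meaningful once sampling noise of the empirical CDF itself
    (~0.19 at n=50) drops below it.
    """
    pvals = []
    frac_below = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n = 500
        metric = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        sets = [
            GeneSet(f"s{k}", frozenset(rng.choice(metric.index, 15, replace=False)))
            for k in range(50)
        ]
        res = preranked_gsea(metric, sets, nperm=1000, seed=seed)
        pvals.append(res["p"].to_numpy())
        frac_below.append((res["p"] < 0.05).mean())
    p = np.sort(np.concatenate(pvals))
    grid = np.arange(1, len(p) + 1) / len(p)
    assert np.max(np.abs(p - grid)) < 0.1
    # type-I calibration: rejection rate at 0.05 within binomial noise
    se = np.sqrt(0.05 * 0.95 / len(p))
    assert abs(np.mean(frac_below) - 0.05) < 3 * se + 1e-12


def test_preranked_requires_sets_and_permutations():
    r = ranked(10)
    with pytest.raises(ValidationError):
        preranked_gsea(r, [], nperm=1000)
    with pytest.raises(ValidationError):
        preranked_gsea(r, [GeneSet("s", frozenset({"g0"}))], nperm=10)


def test_ssgsea_hand_computed_tiny_case():
    # N=4, set = top gene, alpha=0: sum of (ECDF_hit - ECDF_miss)
    # = (1-0) + (1-1/3) + (1-2/3) + (1-1) = 2
    em = ExpressionMatrix(pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0]}, index=["a", "b", "c", "d"]
    ).assign(s2=[4.0, 3.0, 2.0, 1.0]))
    scores = ssgsea(em, [GeneSet("t", frozenset({"a"}))], alpha=0.0)
    assert scores.loc["s1", "t"] == pytest.approx(2.0, abs=1e-12)


def test_ssgsea_identical_samples_identical_rows():
    rng = np.random.default_rng(6)
    col = rng.lognormal(2, 1, size=20)
    em = ExpressionMatrix(pd.DataFrame(
        {"s1": col, "s2": col}, index=[f"g{i}" for i in range(20)]
    ))
    gs = GeneSet("s", frozenset({"g1", "g5", "g9"}))
    scores = ssgsea(em, [gs])
    assert scores.loc["s1", "s"] == pytest.approx(scores.loc["s2", "s"], abs=1e-12)


def test_ssgsea_rank_only_dependence():
    """Scaling one sample's expression (a constant on the log scale) leaves
    its ssGSEA scores unchanged."""
    rng = np.random.default_rng(8)
    col = rng.lognormal(2, 1, size=20)
    em1 = ExpressionMatrix(pd.DataFrame({"s1": col}, index=[f"g{i}" for i in range(20)]))
    em2 = ExpressionMatrix(pd.DataFrame({"s1": col * 8.0}, index=[f"g{i}" for i in range(20)]))
    gs = GeneSet("s", frozenset({"g3", "g4", "g11"}))
    assert ssgsea(em1, [gs]).iloc[0, 0] == pytest.approx(
        ssgsea(em2, [gs]).iloc[0, 0], abs=1e-12
    )


def test_ssgsea_absent_set_missing_with_warning(caplog, random_expr):
    with caplog.at_level("WARNING", logger="tme_profiler.enrichment"):
        scores = ssgsea(random_expr, [GeneSet("none", frozenset({"ZZZ"}))])
    assert scores["none"].isna().all()
    assert any("no member" in r.message for r in caplog.records)


def test_ssgsea_oxphos_direction_on_planted_cohort(small_cohort):
    sets = toy_metabolic_sets()
    scores = ssgsea(small_cohort.expression, [sets["OXPHOS"]])
    groups = small_cohort.manifest.groups()
    mbm = scores.loc[groups[groups == "MBM"].index, "OXPHOS"].mean()
    ecm = scores.loc[groups[groups == "ECM"].index, "OXPHOS"].mean()
    assert mbm > ecm


def test_rank_genes_tie_break_by_symbol():
    metric = pd.Series([1.0, 2.0, 1.0], index=["b", "c", "a"])
    assert rank_genes(metric).index.tolist() == ["c", "a", "b"]
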