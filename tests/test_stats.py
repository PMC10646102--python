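"""Group tests, BH correction, proportion tests, correlations, DEGs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from tme_profiler.cohort_io import CohortManifest, ExpressionMatrix, ValidationError
from tme_profiler.stats import (
    bh_adjust,
    correlation_matrix,
    deg,
    kruskal_bh,
    mann_whitney,
    proportion_test,
)
from tme_profiler.synthetic import generate_cohort

from conftest import small_config


def brute_force_bh(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p-value
        running_min = min(running_min, p[idx] * m / i)
        adj[idx] = running_min
    return adj


class TestBh:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-9)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_monotone(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestKruskal:
    def test_identical_groups_null(self):
        data = pd.DataFrame({"v": [3.0] * 9}, index=[f"s{i}" for i in range(9)])
        groups = pd.Series(["PCM"] * 3 + ["MBM"] * 3 + ["ECM"] * 3, index=data.index)
        res = kruskal_bh(data, groups)
        assert res["statistic"].iloc[0] == 0.0
        assert res["raw_p"].iloc[0] == 1.0

    def test_two_group_direction_matches_rank_sum(self):
        """Larger shifts give smaller KW p, consistent with the rank-sum test."""
        idx = [f"s{i}" for i in range(12)]
        groups = pd.Series(["PCM"] * 6 + ["MBM"] * 6, index=idx)
        small_shift = pd.DataFrame(
            {"v": [1, 2, 3, 4, 5, 6, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5]}, index=idx)
        large_shift = pd.DataFrame(
            {"v": [1, 2, 3, 4, 5, 6, 11, 12, 13, 14, 15, 16]}, index=idx)
        p_small = kruskal_bh(small_shift, groups)["raw_p"].iloc[0]
        p_large = kruskal_bh(large_shift, groups)["raw_p"].iloc[0]
        assert p_large < p_small
        _, p_mw = mann_whitney(large_shift["v"][:6], large_shift["v"][6:])
        assert p_mw < 0.05 and p_large < 0.05

    def test_family_is_one_call(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(30)]
        groups = pd.Series(["PCM"] * 10 + ["MBM"] * 10 + ["ECM"] * 10, index=idx)
        data = pd.DataFrame(rng.normal(size=(30, 5)),
                            index=idx, columns=list("abcde"))
        res = kruskal_bh(data, groups)
        np.testing.assert_allclose(
            res["adj_p"], bh_adjust(res["raw_p"].to_numpy()), atol=1e-12)

    def test_small_group_rejected(self):
        data = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        groups = pd.Series(["PCM", "PCM", "MBM"], index=data.index)
        with pytest.raises(ValidationError):
            kruskal_bh(data, groups)


class TestMannWhitney:
    def test_identical_multisets_null(self):
        _, p = mann_whitney([1, 2, 3, 3], [1, 2, 3, 3])
        assert p >= 0.99

    def test_extreme_separation_exact_p(self):
        """Most extreme U on 3 vs 3: exact two-sided p = 2/20."""
        _, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(2 / 20)

    def test_exact_matches_enumeration(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 8.0]
        _, p = mann_whitney(a, b)
        # enumerate all C(6,3) labelings of the pooled sample
        pooled = sorted(a + b)
        u_obs = sum(1 for x in a for y in b if x > y)
        n = len(a)
        us = []
        for combo in itertools.combinations(range(6), n):
            aa = [pooled[i] for i in combo]
            bb = [pooled[i] for i in range(6) if i not in combo]
            us.append(sum(1 for x in aa for y in bb if x > y))
        mean_u = np.mean(us)
        expected = np.mean([abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us])
        assert p == pytest.approx(expected, abs=1e-9)

    def test_monotone_transform_invariance(self):
        a = [1.0, 5.0, 9.0, 2.0]
        b = [3.0, 7.0, 11.0, 13.0]
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([1.0], [1.0, 2.0])


class TestProportion:
    def test_perfect_homogeneity(self):
        branch, p = proportion_test(np.array([[5, 5], [5, 5]]))
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[10, 0], [0, 10]])
        branch, p = proportion_test(table)
        assert branch == "fisher"
        # enumerate the hypergeometric: P(X=k) for k successes in first row
        probs = [sps.hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        p_obs = probs[10]
        expected = sum(q for q in probs if q <= p_obs + 1e-12)
        assert p == pytest.approx(expected, abs=1e-9)
        assert p == pytest.approx(2 / 184756, abs=1e-9)

    def test_chi2_branch_for_large_2x3(self):
        branch, p = proportion_test(np.array([[20, 30, 25], [22, 28, 31]]))
        assert branch == "chi2"

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            proportion_test(np.array([[0, 0], [5, 5]]))

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            proportion_test(np.array([[1.5, 2.0], [3.0, 4.0]]))


class TestCorrelation:
    def test_identity_and_reversal(self):
        x = pd.DataFrame({"x": np.arange(8, dtype=float)})
        res = correlation_matrix(x, x.rename(columns={"x": "y"}), method="spearman")
        assert res["rho"].iloc[0, 0] == pytest.approx(1.0)
        assert bool(res["mask"].iloc[0, 0]) is False
        rev = x.iloc[::-1].reset_index(drop=True).rename(columns={"x": "y"})
        res2 = correlation_matrix(x, rev, method="spearman")
        assert res2["rho"].iloc[0, 0] == pytest.approx(-1.0)

    def test_spearman_matches_d_squared_formula(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.permutation(8).astype(float))
        y = pd.Series(rng.permutation(8).astype(float))
        res = correlation_matrix(x.to_frame("x"), y.to_frame("y"))
        d = sps.rankdata(x) - sps.rankdata(y)
        expected = 1 - 6 * np.sum(d**2) / (8 * (8**2 - 1))
        assert res["rho"].iloc[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_too_few_pairs_missing(self, caplog):
        x = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan, np.nan]})
        y = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0]})
        with caplog.at_level("WARNING", logger="tme_profiler.stats"):
            res = correlation_matrix(x, y)
        assert np.isnan(res["rho"].iloc[0, 0])

    def test_mask_marks_nonsignificant(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame({"x": rng.normal(size=20)})
        y = pd.DataFrame({"y": rng.normal(size=20)})
        res = correlation_matrix(x, y, alpha=1e-6)
        assert bool(res["mask"].iloc[0, 0]) is True


class TestDeg:
    def _cohort(self):
        rows = [{"sample_id": f"A{i}", "group": "MBM"} for i in range(10)]
        rows += [{"sample_id": f"B{i}", "group": "PCM"} for i in range(10)]
        return CohortManifest(pd.DataFrame(rows))

    def test_identical_group_means_zero_log2fc(self):
        manifest = self._cohort()
        half = np.tile(np.arange(10, dtype=float), (3, 1))
        values = np.hstack([half, half])  # both groups see identical values
        expr = ExpressionMatrix(pd.DataFrame(
            values, index=["g1", "g2", "g3"], columns=manifest.sample_ids))
        res = deg(expr, manifest, "MBM", "PCM")
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)

    def test_doubling_approaches_log2fc_one(self):
        manifest = self._cohort()
        rng = np.random.default_rng(4)
        base = rng.uniform(1e4, 1e5, size=(5, 10))
        values = np.hstack([2 * base, base])
        expr = ExpressionMatrix(pd.DataFrame(
            values, index=[f"g{i}" for i in range(5)], columns=manifest.sample_ids))
        res = deg(expr, manifest, "MBM", "PCM")
        np.testing.assert_allclose(res["log2fc"], 1.0, atol=1e-3)

    def test_planted_upregulated_gene_detected(self):
        """A 4x planted MBM up-shift is recovered as a significant positive
        DEG in nearly all seeds."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = small_config(
                n_per_group={"PCM": 30, "MBM": 30, "ECM": 2},
                n_genes=330, seed=600 + seed,
                signature_shift={("MBM", "tnf"): 2.0},  # 4x on TNF
                pten_angiogenesis_shift=0.0,
            )
            cohort = generate_cohort(cfg)
            res = deg(cohort.expression, cohort.manifest, "MBM", "PCM")
            row = res.set_index("gene").loc["TNF"]
            if row["significant"] and row["log2fc"] > 0:
                hits += 1
        assert hits >= 24

    def test_global_null_fdr_control(self):
        """Without planted differences, few genes pass BH at 5%."""
        cfg = small_config(
            n_per_group={"PCM": 30, "MBM": 30, "ECM": 2},
            n_genes=330, seed=900,
            signature_shift={}, pten_angiogenesis_shift=0.0,
        )
        cohort = generate_cohort(cfg)
        res = deg(cohort.expression, cohort.manifest, "MBM", "PCM")
        assert res["significant"].mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(res))
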