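"""Agreement scores, test routing, effect sizes, BH-FDR and edgewise battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from morphotype.stats import (
    adjusted_rand,
    agreement_scores,
    bh_fdr,
    cohens_d,
    compare_categorical,
    compare_continuous,
    edgewise_comparison,
    homogeneity_completeness,
    nmi,
    phenotype_battery,
)


def _entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return -(p * np.log(p)).sum()


def _mutual_info(a, b):
    mi = 0.0
    n = a.size
    for u in np.unique(a):
        for v in np.unique(b):
            nij = np.sum((a == u) & (b == v))
            if nij:
                mi += (nij / n) * np.log(n * nij / (np.sum(a == u) * np.sum(b == v)))
    return mi


class TestAgreement:
    def test_nmi_matches_entropy_oracle(self, rng):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 4, 60)
        expected = _mutual_info(a, b) / (0.5 * (_entropy(a) + _entropy(b)))
        assert nmi(a, b) == pytest.approx(expected, abs=1e-10)

    def test_nmi_identical_partitions_is_one(self, rng):
        a = rng.integers(0, 3, 40)
        a[:3] = [0, 1, 2]  # ensure all classes present
        assert nmi(a, a) == pytest.approx(1.0)
        assert nmi(a, 2 - a) == pytest.approx(1.0)  # invariant to relabeling

    def test_nmi_constant_partition_is_zero(self, rng):
        a = rng.integers(0, 3, 30)
        assert nmi(a, np.zeros(30)) == 0.0
        assert nmi(np.ones(30), a) == 0.0

    def test_ari_pair_counting_oracle(self, rng):
        """ARI from the contingency-table pair-counting formula."""
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 3, 50)

        def comb2(x):
            return x * (x - 1) / 2

        table = pd.crosstab(a, b).to_numpy()
        sum_ij = comb2(table).sum()
        sum_a = comb2(table.sum(axis=1)).sum()
        sum_b = comb2(table.sum(axis=0)).sum()
        expected_idx = sum_a * sum_b / comb2(50)
        max_idx = (sum_a + sum_b) / 2
        oracle = (sum_ij - expected_idx) / (max_idx - expected_idx)
        assert adjusted_rand(a, b) == pytest.approx(oracle, abs=1e-10)

    def test_ari_independent_partitions_near_zero(self, rng):
        vals = [adjusted_rand(rng.integers(0, 2, 200), rng.integers(0, 2, 200)) for _ in range(50)]
        assert abs(np.mean(vals)) < 0.02

    def test_homogeneity_completeness_oracles(self):
        """Refinement: splitting one true cluster keeps homogeneity 1 and
        drops completeness to 1 - H(truth|pred)/H(truth) by hand."""
        truth = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pred = np.array([0, 0, 1, 1, 2, 2, 2, 2])
        h, c = homogeneity_completeness(truth, pred)
        assert h == pytest.approx(1.0)
        # H(truth) = log 2; H(truth | pred) = 0 => completeness = MI/H(pred)
        expected_c = _mutual_info(truth, pred) / _entropy(pred)
        assert c == pytest.approx(expected_c, abs=1e-10)

    def test_agreement_scores_bundle(self, rng):
        a = rng.integers(0, 2, 40)
        s = agreement_scores(a, a)
        assert s.nmi == pytest.approx(1.0)
        assert s.adjusted_rand == pytest.approx(1.0)
        assert s.homogeneity == pytest.approx(1.0)
        assert s.completeness == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi(np.zeros(5), np.zeros(6))


class TestCompareContinuous:
    def test_routes_normal_two_group_to_t(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        labels = np.repeat([0, 1], 50)
        res = compare_continuous(vals, labels)
        assert res.test == "t"
        stat, p = sps.ttest_ind(vals[:50], vals[50:], equal_var=False)
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.effect_size == pytest.approx(cohens_d(vals[:50], vals[50:]))

    def test_routes_skewed_two_group_to_kruskal(self, rng):
        vals = np.concatenate([rng.exponential(1, 60), rng.exponential(2, 60)])
        labels = np.repeat([0, 1], 60)
        res = compare_continuous(vals, labels)
        assert res.test == "kruskal-wallis"
        stat, p = sps.kruskal(vals[:60], vals[60:])
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_three_groups_always_kruskal(self, rng):
        vals = rng.normal(0, 1, 90)
        labels = np.repeat([0, 1, 2], 30)
        res = compare_continuous(vals, labels)
        assert res.test == "kruskal-wallis"

    def test_force_test_override(self, rng):
        vals = np.concatenate([rng.exponential(1, 30), rng.exponential(1, 30)])
        labels = np.repeat([0, 1], 30)
        res = compare_continuous(vals, labels, force_test="t")
        assert res.test == "t"

    def test_routing_type_one_error_controlled(self, rng):
        """Under the two-group null the routed test rejects at ~alpha."""
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            vals = rng.normal(0, 1, 60)
            labels = np.repeat([0, 1], 30)
            if compare_continuous(vals, labels).p_value < 0.05:
                rejections += 1
        # binomial(400, 0.05): 3 sigma ~ 0.033
        assert rejections / n_sims < 0.09

    def test_identical_values_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            res = compare_continuous(np.ones(20), np.repeat([0, 1], 10))
        assert res.p_value == 1.0

    def test_group_summaries_medians(self):
        vals = np.concatenate([np.arange(5.0), np.arange(5.0) + 10])
        res = compare_continuous(vals, np.repeat(["a", "b"], 5))
        assert res.group_summaries["a"]["median"] == 2.0
        assert res.group_summaries["b"]["median"] == 12.0
        assert res.group_summaries["a"]["iqr"] == 2.0

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_continuous(np.arange(5.0), np.array([0, 0, 0, 1, 1]))


class TestCompareCategorical:
    def test_two_by_two_closed_form(self):
        """[[10, 20], [20, 10]]: chi2 = n (ad - bc)^2 / (r1 r2 c1 c2) = 6.6667."""
        res = compare_categorical([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(60 * (10 * 10 - 20 * 20) ** 2 / (30 * 30 * 30 * 30), abs=1e-10)
        assert res.statistic == pytest.approx(20 / 3, abs=1e-10)

    def test_independent_table_statistic_zero(self):
        res = compare_categorical([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_sex_by_group_worked_example(self):
        """Male:female 204:58 vs 135:36 vs 74:58 gives chi2 close to 25.40."""
        res = compare_categorical([[204, 58], [135, 36], [74, 58]])
        assert res.statistic == pytest.approx(25.40, rel=0.01)
        assert res.p_value < 1e-4

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="column 1"):
            compare_categorical([[5, 0], [3, 0]])
        with pytest.raises(ValueError, match="row 0"):
            compare_categorical([[0, 0], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical([[1.5, 2], [3, 4]])


class TestCohensD:
    def test_hand_example(self):
        """{1,2,3} vs {2,3,4}: means differ by 1, pooled SD 1 -> d = -1."""
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0, abs=1e-12)

    def test_sign_convention(self):
        assert cohens_d([2, 3, 4], [1, 2, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        assert cohens_d(7 * a, 7 * b) == pytest.approx(cohens_d(a, b), abs=1e-10)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestBhFdr:
    def test_textbook_oracle(self):
        """p = [.01, .011, .02, .04, .5], m=5: adjusted by the step-up recursion."""
        p = np.array([0.01, 0.011, 0.02, 0.04, 0.5])
        adjusted, rejected = bh_fdr(p, q=0.05)
        # raw p*m/rank: [.05, .0275, .0333, .05, .5]; enforce monotone from the top
        np.testing.assert_allclose(adjusted, [0.0275, 0.0275, 0.03333333, 0.05, 0.5], atol=1e-8)
        np.testing.assert_array_equal(rejected, [True, True, True, True, False])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 200)
        adjusted, rejected = bh_fdr(p, q=0.05)
        rej_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adjusted, adj_sm, atol=1e-12)
        np.testing.assert_array_equal(rejected, rej_sm)

    def test_all_null_rarely_rejects(self, rng):
        any_rej = 0
        for _ in range(100):
            _, rejected = bh_fdr(rng.uniform(0, 1, 50), q=0.05)
            any_rej += rejected.any()
        assert any_rej / 100 < 0.12  # FWER under independence <= q

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestEdgewise:
    def _stack(self, rng, labels, shifted_edges=(), delta=0.5, r=6):
        n = labels.size
        stack = np.clip(rng.uniform(0.3, 0.7, (n, r, r)), 0, 1)
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for a, b in shifted_edges:
            stack[labels == 1, a, b] += delta
            stack[labels == 1, b, a] += delta
        idx = np.arange(r)
        stack[:, idx, idx] = 1.0
        return stack

    def test_null_controls_fdp(self, rng):
        labels = np.repeat([0, 1], 40)
        n_any = 0
        for _ in range(30):
            frame = edgewise_comparison(self._stack(rng, labels), labels)
            n_any += frame["significant"].any()
        assert n_any / 30 < 0.2

    def test_planted_edges_detected_with_direction(self, rng):
        labels = np.repeat([0, 1], 60)
        shifted = [(0, 1), (2, 3)]
        frame = edgewise_comparison(self._stack(rng, labels, shifted, delta=0.6), labels)
        frame = frame.set_index(["region_a", "region_b"])
        for a, b in shifted:
            row = frame.loc[(f"R{a:03d}", f"R{b:03d}")]
            assert row["significant"]
            assert row["median_diff"] < 0  # cluster 0 minus cluster 1
            assert row["cohens_d"] < -1
        assert frame["significant"].sum() <= len(shifted) + 2

    def test_statistic_matches_scipy_per_edge(self, rng):
        labels = np.repeat([0, 1], 20)
        stack = self._stack(rng, labels, r=4)
        frame = edgewise_comparison(stack, labels, regions=list("ABCD"))
        w = stack[:, 0, 1]
        stat, p = sps.kruskal(w[labels == 0], w[labels == 1])
        row = frame[(frame.region_a == "A") & (frame.region_b == "B")].iloc[0]
        assert row["statistic"] == pytest.approx(stat, abs=1e-10)
        assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_phenotype_battery_shape_and_detection(self, rng):
        labels = np.repeat([0, 1], 50)
        pheno = pd.DataFrame(
            {
                "shifted": rng.normal(0, 1, 100) + labels * 1.5,
                "null_a": rng.normal(0, 1, 100),
                "null_b": rng.exponential(1, 100),
            }
        )
        frame = phenotype_battery(pheno, labels)
        assert list(frame["variable"]) == ["shifted", "null_a", "null_b"]
        assert bool(frame.loc[frame.variable == "shifted", "significant"].iloc[0])
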