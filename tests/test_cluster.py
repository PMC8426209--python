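import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import fisher_exact, hypergeom

from immunopanel.cluster import (
    ClusterError, association_test, bicluster, center_rows, contingency_table,
    hcluster, label_hot_cold,
)
from immunopanel.scores import TOTAL_TILS
from immunopanel.synthetic import SimulationConfig, simulate_cohort


def oracle_fisher_2x2(table):
    """Independent brute-force two-sided Fisher p: enumerate every 2x2 table
    with the observed margins via the hypergeometric pmf."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        p = hypergeom.pmf(x, n, c1, r1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestCenterRows:
    def test_known_rows(self):
        out = center_rows(np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))
        np.testing.assert_allclose(out[0], [-1, 0, 1])
        np.testing.assert_allclose(out[1], [0, 0, 0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(5, 8))
        np.testing.assert_allclose(center_rows(center_rows(m)), center_rows(m), atol=1e-12)

    def test_dataframe_row_means_zero(self, cell_scores):
        centered = center_rows(cell_scores)
        assert np.abs(centered.mean(axis=1)).max() < 1e-12


class TestHCluster:
    def test_separated_blobs_recovered(self):
        m = pd.DataFrame(
            np.hstack([np.zeros((3, 4)), np.full((3, 4), 10.0)]),
            columns=[f"s{i}" for i in range(8)],
        )
        labels = hcluster(m, axis="columns", k=2).labels
        assert labels.iloc[:4].nunique() == 1 and labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[7]

    def test_k1_single_cluster(self, cell_scores):
        assert hcluster(cell_scores, k=1).labels.nunique() == 1

    @pytest.mark.parametrize("k", [0, 99])
    def test_k_out_of_range(self, cell_scores, k):
        with pytest.raises(ClusterError):
            hcluster(cell_scores.iloc[:, :10], k=k)

    def test_permutation_stability(self, cell_scores):
        """Shuffling sample order changes labels only up to relabeling."""
        rng = np.random.default_rng(1)
        perm = rng.permutation(cell_scores.columns)
        a = hcluster(cell_scores, k=3).labels
        b = hcluster(cell_scores[perm], k=3).labels
        pairs_a = {frozenset(p) for p in itertools.combinations(a.index, 2)
                   if a[p[0]] == a[p[1]]}
        pairs_b = {frozenset(p) for p in itertools.combinations(b.index, 2)
                   if b[p[0]] == b[p[1]]}
        assert pairs_a == pairs_b


class TestHotColdLabels:
    def _assign(self, labels):
        s = pd.Series(labels, index=[f"s{i}" for i in range(len(labels))], name="cluster")
        from immunopanel.cluster import ClusterAssignment
        return ClusterAssignment(labels=s, linkage_matrix=np.empty((0, 4)))

    def test_higher_mean_is_hot(self):
        assign = self._assign([1, 1, 2, 2])
        til = pd.Series([5.0, 5.0, 2.0, 2.0], index=assign.labels.index)
        states = label_hot_cold(assign, til)
        assert list(states) == ["hot", "hot", "cold", "cold"]

    def test_label_invariance_under_cluster_relabel(self):
        til = pd.Series([5.0, 5.0, 2.0, 2.0], index=[f"s{i}" for i in range(4)])
        a = label_hot_cold(self._assign([1, 1, 2, 2]), til)
        b = label_hot_cold(self._assign([2, 2, 1, 1]), til)
        pd.testing.assert_series_equal(a, b)

    def test_tie_labels_larger_cluster_cold(self, caplog):
        assign = self._assign([1, 1, 1, 2, 2])
        til = pd.Series([3.0] * 5, index=assign.labels.index)
        with caplog.at_level("WARNING"):
            states = label_hot_cold(assign, til)
        assert list(states) == ["cold"] * 3 + ["hot"] * 2
        assert any("tie" in m for m in caplog.messages)

    def test_needs_two_clusters(self, cell_scores):
        with pytest.raises(ClusterError):
            label_hot_cold(hcluster(cell_scores, k=3), cell_scores.loc[TOTAL_TILS])


class TestAssociationTest:
    def test_study_worked_example(self):
        """Cold/hot x (EGFR-Ex20mut, EGFR/ERBB2wt) counts 10,3 / 9,17 give the
        reported two-sided Fisher P = 0.018 (enumeration value 0.0187)."""
        p = association_test([[10, 3], [9, 17]]).pvalue
        assert p == pytest.approx(0.0187, abs=1e-3)
        assert p == pytest.approx(oracle_fisher_2x2([[10, 3], [9, 17]]), abs=1e-12)

    def test_flat_table(self):
        assert association_test([[1, 1], [1, 1]]).pvalue == pytest.approx(1.0)

    def test_diagonal_2_2(self):
        # margins (2,2)/(2,2) admit 3 tables; the two diagonal ones are as
        # extreme as observed -> p = 2/6 = 1/3
        assert association_test([[2, 0], [0, 2]]).pvalue == pytest.approx(1 / 3)

    def test_degenerate_margin_p_one(self, caplog):
        with caplog.at_level("WARNING"):
            res = association_test([[0, 0], [3, 4]])
        assert res.pvalue == 1.0
        assert any("degenerate" in m for m in caplog.messages)

    def test_matches_oracle_on_random_2x2(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            p = association_test(t).pvalue
            assert abs(p - oracle_fisher_2x2(t)) <= 1e-10, t
            assert abs(p - fisher_exact(t)[1]) <= 1e-10, t
            checked += 1

    def test_rxc_exact_against_scipy_2x2_collapse(self):
        # 2x3 with an empty-ish structure: verify against the sum over the
        # multivariate hypergeometric by direct enumeration
        table = np.array([[3, 1, 4], [2, 5, 0]])
        r, c = table.sum(axis=1), table.sum(axis=0)
        n = table.sum()

        def prob(t):
            from math import comb as mcomb
            return (
                np.prod([mcomb(int(c[j]), int(t[0, j])) for j in range(3)])
                / mcomb(int(n), int(r[0]))
            )

        p_obs = prob(table)
        total = 0.0
        for x0 in range(min(r[0], c[0]) + 1):
            for x1 in range(min(r[0] - x0, c[1]) + 1):
                x2 = r[0] - x0 - x1
                if 0 <= x2 <= c[2]:
                    t = np.array([[x0, x1, x2], [c[0] - x0, c[1] - x1, c[2] - x2]])
                    p = prob(t)
                    if p <= p_obs * (1 + 1e-7):
                        total += p
        assert association_test(table).pvalue == pytest.approx(total, abs=1e-10)

    def test_monte_carlo_fallback_flagged_and_close(self):
        table = [[10, 3], [9, 17]]
        res = association_test(table, max_tables=2, n_mc=40000, seed=5)
        assert res.method.startswith("monte_carlo")
        assert res.pvalue == pytest.approx(0.0187, abs=0.005)

    def test_rejects_bad_tables(self):
        with pytest.raises(ClusterError):
            association_test([[1, 2]])
        with pytest.raises(ClusterError):
            association_test([[-1, 2], [3, 4]])


class TestBiclusterAndRecovery:
    def test_bicluster_names_by_decreasing_size(self, normalized):
        sub = normalized.iloc[:30]
        s_labels, g_labels = bicluster(sub, k_samples=3, k_genes=3)
        s_sizes = s_labels.value_counts()
        assert list(s_sizes.index) == sorted(s_sizes.index, key=lambda x: (-s_sizes[x], x))
        assert set(g_labels) <= {"G1", "G2", "G3"}

    def test_hot_cold_recovery_on_default_cohort(self, default_cohort, cell_scores, marker_catalog):
        counts, probes, samples, truth = default_cohort
        pops = list(marker_catalog)
        assign = hcluster(center_rows(cell_scores.loc[pops]), axis="columns", k=2)
        states = label_hot_cold(assign, cell_scores.loc[TOTAL_TILS])
        agree = (states == truth.samples["state"]).mean()
        assert agree >= 0.95

    def test_contingency_table_shape(self, default_cohort, cell_scores, marker_catalog):
        counts, probes, samples, truth = default_cohort
        pops = list(marker_catalog)
        assign = hcluster(center_rows(cell_scores.loc[pops]), axis="columns", k=2)
        states = label_hot_cold(assign, cell_scores.loc[TOTAL_TILS])
        table = contingency_table(states, samples["group"])
        assert table.shape == (2, 4)
        assert table.to_numpy().sum() == 98
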