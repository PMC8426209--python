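import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from immunopanel.diffexp import (
    DiffExpError, bh_adjust, de_analysis, kruskal_matrix, kruskal_omnibus,
    pairwise_wilcoxon, signed_fold_change, significant_sets, venn_partition,
)
from immunopanel.normalization import normalize
from immunopanel.synthetic import (
    GROUP_EGFR_EX20, GROUP_WT, PlantedEffect, SimulationConfig, null_config,
    simulate_cohort,
)


def bh_oracle(p):
    """Brute-force step-up definition: adj_i = min_{j: p_(j) >= p_(i)} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


def wilcoxon_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating every assignment of ranks."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:nx].sum()
    mean = nx * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


class TestKruskal:
    def test_all_identical_values(self):
        vals = pd.Series([5.0] * 6, index=list("abcdef"))
        grp = pd.Series(["x", "x", "y", "y", "z", "z"], index=vals.index)
        assert kruskal_omnibus(vals, grp) == (0.0, 1.0)

    def test_maximal_separation_matches_rank_formula(self):
        vals = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"), dtype=float)
        grp = pd.Series(["x", "x", "y", "y", "z", "z"], index=vals.index)
        h, p = kruskal_omnibus(vals, grp)
        # direct computation: H = 12/(n(n+1)) sum R_j^2/n_j - 3(n+1)
        h_direct = 12 / (6 * 7) * ((1 + 2) ** 2 / 2 + (3 + 4) ** 2 / 2 + (5 + 6) ** 2 / 2) - 3 * 7
        assert h == pytest.approx(h_direct)
        assert p == pytest.approx(stats.chi2.sf(h_direct, df=2))

    def test_small_group_rejected(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        grp = pd.Series(["x", "y", "y"], index=vals.index)
        with pytest.raises(DiffExpError):
            kruskal_omnibus(vals, grp)

    def test_vectorized_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(np.round(rng.normal(size=(40, 98)), 1),
                         columns=[f"s{i}" for i in range(98)])
        g = pd.Series(np.repeat(list("abcd"), [19, 13, 40, 26]), index=X.columns)
        vec = kruskal_matrix(X, g)
        for i in range(40):
            h_ref, p_ref = stats.kruskal(*[X.iloc[i][(g == k).values] for k in "abcd"])
            assert vec["H"].iloc[i] == pytest.approx(h_ref, abs=1e-10)
            assert vec["p"].iloc[i] == pytest.approx(p_ref, abs=1e-12)

    def test_vectorized_constant_row(self):
        X = pd.DataFrame([[1.0] * 8], columns=[f"s{i}" for i in range(8)])
        g = pd.Series(["a"] * 4 + ["b"] * 4, index=X.columns)
        out = kruskal_matrix(X, g)
        assert out["H"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0


class TestWilcoxon:
    def test_identical_values_p_one(self):
        vals = pd.Series([2.0] * 6, index=list("abcdef"))
        grp = pd.Series(["x"] * 3 + ["y"] * 3, index=vals.index)
        assert pairwise_wilcoxon(vals, grp, [("x", "y")])[("x", "y")] == 1.0

    def test_most_extreme_exact_p(self):
        """[1,2,3] vs [10,11,12] is the most extreme of C(6,3)=20 orderings:
        two-sided exact p = 2/20 = 0.1."""
        vals = pd.Series([1, 2, 3, 10, 11, 12], index=list("abcdef"), dtype=float)
        grp = pd.Series(["x"] * 3 + ["y"] * 3, index=vals.index)
        assert pairwise_wilcoxon(vals, grp, [("x", "y")])[("x", "y")] == pytest.approx(0.1)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
        grp = pd.Series(["x"] * 5 + ["y"] * 7, index=vals.index)
        p1 = pairwise_wilcoxon(vals, grp, [("x", "y")])[("x", "y")]
        p2 = pairwise_wilcoxon(vals, grp, [("y", "x")])[("y", "x")]
        assert p1 == pytest.approx(p2)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            vals = pd.Series(np.concatenate([x, y]),
                             index=[f"s{i}" for i in range(11)])
            grp = pd.Series(["x"] * 5 + ["y"] * 6, index=vals.index)
            p = pairwise_wilcoxon(vals, grp, [("x", "y")])[("x", "y")]
            assert p == pytest.approx(wilcoxon_oracle(x, y), abs=1e-12)


class TestBH:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_singleton_identity(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_bounds_property(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(DiffExpError):
            bh_adjust([0.5, 1.5])


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(5.0, 5.0, 1.0), (3.0, 5.0, -4.0), (6.322, 5.0, 2.5)]
    )
    def test_known_values(self, a, b, expected):
        assert signed_fold_change(a, b) == pytest.approx(expected, rel=1e-3)

    @given(st.floats(min_value=-8, max_value=8), st.floats(min_value=-8, max_value=8))
    def test_antisymmetry(self, a, b):
        if abs(a - b) < 1e-9:  # FC of an (effectively) zero difference is +1 by convention
            return
        assert signed_fold_change(a, b) == pytest.approx(-signed_fold_change(b, a))


class TestVenn:
    def test_worked_example(self):
        cells = venn_partition({"g1", "g2"}, {"g2"}, set())
        assert cells[("A",)] == {"g1"}
        assert cells[("A", "B")] == {"g2"}
        assert all(not v for k, v in cells.items() if k not in (("A",), ("A", "B")))

    def test_identical_sets_all_triple(self):
        s = {"x", "y"}
        cells = venn_partition(s, s, s)
        assert cells[("A", "B", "C")] == s
        assert sum(len(v) for k, v in cells.items() if k != ("A", "B", "C")) == 0

    def test_cells_partition_the_union(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        a, b, c = (set(rng.choice(genes, size=rng.integers(0, 25), replace=False))
                   for _ in range(3))
        cells = venn_partition(a, b, c)
        union = set().union(*cells.values())
        assert union == a | b | c
        assert sum(len(v) for v in cells.values()) == len(union)  # disjoint


@pytest.fixture(scope="module")
def de_run():
    cfg = null_config(SimulationConfig(n_genes=120, seed=21))
    cfg.planted_effects = [
        PlantedEffect("GENE_0005", GROUP_EGFR_EX20, GROUP_WT, -2.0)
    ]
    counts, probes, samples, _ = simulate_cohort(cfg)
    norm = normalize(counts, probes)
    return de_analysis(norm, samples, reference=GROUP_WT, fdr=0.05), norm, samples


class TestDEAnalysis:
    def test_adjusted_not_below_raw(self, de_run):
        de, _, _ = de_run
        ok = de["q_omnibus"] >= de["p_omnibus"] - 1e-12
        assert ok.all()

    def test_flags_consistent_with_threshold(self, de_run):
        de, _, _ = de_run
        assert (de["sig_omnibus"] == (de["q_omnibus"] <= 0.05)).all()

    def test_planted_gene_found_with_negative_fc(self, de_run):
        de, _, _ = de_run
        col = f"sig:{GROUP_EGFR_EX20} vs {GROUP_WT}"
        fc = de.loc["GENE_0005", f"fc:{GROUP_EGFR_EX20} vs {GROUP_WT}"]
        assert bool(de.loc["GENE_0005", col])
        assert fc < -3.0  # planted -2 log2 = 4-fold down

    def test_gating_leaves_nonsignificant_untested(self, de_run):
        de, _, _ = de_run
        pcol = f"p:{GROUP_EGFR_EX20} vs {GROUP_WT}"
        untested = de.loc[~de["sig_omnibus"], pcol]
        assert untested.isna().all()

    def test_significant_sets_split_by_direction(self, de_run):
        de, _, _ = de_run
        pair = (GROUP_EGFR_EX20, GROUP_WT)
        down = significant_sets(de, pair, "down")
        up = significant_sets(de, pair, "up")
        assert "GENE_0005" in down and "GENE_0005" not in up

    def test_invalid_fdr_rejected(self, de_run):
        _, norm, samples = de_run
        with pytest.raises(DiffExpError):
            de_analysis(norm, samples, fdr=1.5)

    def test_cell_score_rows_reuse_machinery(self, cell_scores, default_cohort):
        samples = default_cohort[2]
        de = de_analysis(cell_scores, samples, reference=GROUP_WT)
        assert de.shape[0] == cell_scores.shape[0]
        assert {"H", "p_omnibus", "q_omnibus"} <= set(de.columns)
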