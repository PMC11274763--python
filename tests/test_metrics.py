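import numpy as np
import pandas as pd
import pytest

import fconnet as fc
from fconnet import metrics as M
from conftest import random_graph
from oracles import (
    oracle_assortativity,
    oracle_betweenness,
    oracle_clustering,
    oracle_global_efficiency,
    oracle_local_efficiency,
    oracle_modularity,
    oracle_participation,
    oracle_path_length,
)


def complete(n):
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return a


def star(n_leaves):
    a = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.uint8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def path(n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def cycle(n):
    a = path(n)
    a[0, n - 1] = a[n - 1, 0] = 1
    return a


def two_cliques(k):
    a = np.zeros((2 * k, 2 * k), dtype=np.uint8)
    a[:k, :k] = complete(k)
    a[k:, k:] = complete(k)
    return a


class TestWorkedCases:
    def test_triangle_clustering_is_one(self):
        c, cc = fc.clustering(complete(3))
        np.testing.assert_array_equal(c, [1, 1, 1])
        assert cc == 1.0

    def test_star_has_no_triangles(self):
        c, cc = fc.clustering(star(3))
        assert cc == 0.0 and np.all(c == 0)

    def test_path3_characteristic_length(self):
        _, L = fc.path_length(path(3))
        assert L == pytest.approx(4 / 3)

    def test_complete_graph_length_and_efficiency(self):
        _, L = fc.path_length(complete(4))
        assert L == 1.0
        assert fc.global_efficiency(complete(5)) == 1.0

    def test_empty_graph_efficiencies(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        assert fc.global_efficiency(a) == 0.0
        assert fc.local_efficiency(a)[1] == 0.0

    def test_isolated_node_excluded_from_length_with_warning(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[:3, :3] = complete(3)
        with pytest.warns(UserWarning, match="no reachable partner"):
            li, L = fc.path_length(a)
        assert np.isnan(li[3])
        assert L == 1.0

    def test_path3_betweenness(self):
        b = fc.betweenness(path(3))
        np.testing.assert_allclose(b, [0, 1, 0])

    def test_star_center_betweenness_is_one(self):
        b = fc.betweenness(star(5))
        assert b[0] == pytest.approx(1.0)
        np.testing.assert_allclose(b[1:], 0)

    def test_two_cliques_modularity_is_half(self):
        a = two_cliques(4)
        m = np.array([0] * 4 + [1] * 4)
        assert fc.modularity_q(a, m) == pytest.approx(0.5)

    def test_single_community_matches_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = random_graph(rng, 10, 0.4)
            m = np.zeros(10, dtype=int)
            assert fc.modularity_q(a, m) == pytest.approx(oracle_modularity(a, m), abs=1e-12)

    def test_participation_all_within_module_is_zero(self):
        a = two_cliques(4)
        m = np.array([0] * 4 + [1] * 4)
        y, pc = fc.participation(a, m)
        assert pc == 0.0

    def test_participation_split_edges(self):
        # node 0 with one edge into each of two modules -> y = 0.5
        a = np.zeros((3, 3), dtype=np.uint8)
        a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = 1
        m = np.array([0, 0, 1])
        y, _ = fc.participation(a, m)
        assert y[0] == pytest.approx(0.5)

    def test_star_assortativity_minus_one(self):
        assert fc.assortativity(star(4)) == pytest.approx(-1.0)

    def test_regular_graph_assortativity_undefined(self):
        assert np.isnan(fc.assortativity(cycle(6)))


class TestLouvain:
    def test_two_cliques_partition(self):
        a = two_cliques(4)
        m = fc.louvain_communities(a, seed=0)
        assert len(set(m[:4])) == 1 and len(set(m[4:])) == 1
        assert m[0] != m[4]

    def test_ring_of_four_cliques(self):
        # 4 cliques of 4 joined in a ring by single edges
        k = 4
        a = np.zeros((16, 16), dtype=np.uint8)
        for c in range(4):
            a[c * k:(c + 1) * k, c * k:(c + 1) * k] = complete(k)
        for c in range(4):
            i, j = c * k, ((c + 1) % 4) * k + 1
            a[i, j] = a[j, i] = 1
        m = fc.louvain_communities(a, seed=1)
        assert len(set(m)) == 4
        for c in range(4):
            assert len(set(m[c * k:(c + 1) * k])) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        a = random_graph(rng, 30, 0.2)
        m1 = fc.louvain_communities(a, seed=42)
        m2 = fc.louvain_communities(a, seed=42)
        np.testing.assert_array_equal(m1, m2)

    def test_empty_graph_singletons(self):
        m = fc.louvain_communities(np.zeros((5, 5), dtype=np.uint8))
        assert len(set(m)) == 5


class TestOracleAgreement:
    """Fast implementations equal naive brute-force oracles on random graphs."""

    @pytest.mark.parametrize("seed", range(6))
    def test_all_metrics_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        a = random_graph(rng, n, float(rng.uniform(0.2, 0.6)))
        c, cc = fc.clustering(a)
        oc, occ = oracle_clustering(a)
        np.testing.assert_allclose(c, oc, atol=1e-10)
        with np.errstate(invalid="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                li, L = fc.path_length(a)
        oli, oL = oracle_path_length(a)
        np.testing.assert_allclose(li, oli, atol=1e-10, equal_nan=True)
        assert fc.global_efficiency(a) == pytest.approx(oracle_global_efficiency(a), abs=1e-10)
        el, eloc = fc.local_efficiency(a)
        oel, oeloc = oracle_local_efficiency(a)
        np.testing.assert_allclose(el, oel, atol=1e-10)
        np.testing.assert_allclose(fc.betweenness(a), oracle_betweenness(a), atol=1e-10)
        m = rng.integers(0, 3, size=n)
        assert fc.modularity_q(a, m) == pytest.approx(oracle_modularity(a, m), abs=1e-10)
        y, _ = fc.participation(a, m)
        np.testing.assert_allclose(y, oracle_participation(a, m)[0], atol=1e-10)
        r1, r2 = fc.assortativity(a), oracle_assortativity(a)
        assert (np.isnan(r1) and np.isnan(r2)) or r1 == pytest.approx(r2, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        a = random_graph(rng, 12, 0.35)
        perm = rng.permutation(12)
        ap = a[np.ix_(perm, perm)]
        np.testing.assert_allclose(fc.clustering(ap)[0], fc.clustering(a)[0][perm], atol=1e-12)
        np.testing.assert_allclose(fc.betweenness(ap), fc.betweenness(a)[perm], atol=1e-12)
        assert fc.global_efficiency(ap) == pytest.approx(fc.global_efficiency(a), abs=1e-12)
        r1, r2 = fc.assortativity(ap), fc.assortativity(a)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestNullsAndSmallWorld:
    def test_nulls_preserve_degree_sequence(self):
        rng = np.random.default_rng(2)
        a = random_graph(rng, 30, 0.25)
        null = M.rewired_null(a, 10 * int(a.sum() // 2), np.random.default_rng(0))
        np.testing.assert_array_equal(null.sum(1), a.sum(1))
        assert np.array_equal(null, null.T)
        assert np.all(np.diag(null) == 0)

    def test_zero_swap_identity(self):
        rng = np.random.default_rng(3)
        a = random_graph(rng, 20, 0.3)
        nulls = fc.null_ensemble(a, n_nulls=1, swaps_per_edge=0, seed=0)
        _, cc = fc.clustering(a)
        _, L = fc.path_length(a)
        assert nulls.c_rand == cc
        assert nulls.l_rand == L
        sw = fc.small_worldness(a, nulls)
        assert sw.gamma == 1.0 and sw.lam == 1.0 and sw.sigma == 1.0

    def test_lattice_ring_has_excess_clustering_over_nulls(self):
        # ring lattice n=100, k=4: clustering 0.5, far above rewired nulls
        n, k = 100, 4
        a = np.zeros((n, n), dtype=np.uint8)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                j = (i + d) % n
                a[i, j] = a[j, i] = 1
        nulls = fc.null_ensemble(a, n_nulls=20, swaps_per_edge=10, seed=0)
        _, cc = fc.clustering(a)
        ci = 2 * nulls.c_values.std()
        assert cc > nulls.c_rand + 5 * max(ci, 1e-6)

    def test_too_sparse_to_swap(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        with pytest.raises(ValueError, match="at least 2"):
            fc.null_ensemble(a, n_nulls=1, swaps_per_edge=5, seed=0)


class TestGridAndSubsets:
    def test_metrics_over_grid_shape_and_spot_equality(self, micro_matrices, atlas24):
        cm = micro_matrices[0]
        grid = fc.SparsityGrid((0.2, 0.4))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = fc.metrics_over_grid(
                cm, grid, labels=list(atlas24.labels),
                metrics=("clustering", "global_efficiency"), seed=0,
            )
        assert set(df["sparsity"]) == {0.2, 0.4}
        # spot equality with an independent single-threshold recomputation
        g = fc.binarize_at_sparsity(cm, 0.4)
        _, cc = fc.clustering(g)
        got = df[(df["sparsity"] == 0.4) & (df["metric"] == "clustering") & (df["node"] == fc.GLOBAL)]["value"].item()
        assert got == pytest.approx(cc, abs=1e-12)

    def test_integrated_constant_curve(self):
        rows = []
        for s in fc.default_sparsity_grid():
            rows.append({"subject": "s", "group": "g", "sparsity": s,
                         "metric": "clustering", "node": fc.GLOBAL, "value": 0.7})
        out = fc.integrate_over_sparsity(pd.DataFrame(rows))
        assert out["value"].item() == pytest.approx(0.7 * 0.4)

    def test_roi_subset_metric(self, atlas24):
        rng = np.random.default_rng(4)
        rows = []
        for subj, grp in (("s1", "A"), ("s2", "B")):
            for lab in atlas24.labels:
                rows.append({"subject": subj, "group": grp, "metric": "betweenness",
                             "node": lab, "value": rng.random()})
        table = pd.DataFrame(rows)
        full = fc.roi_subset_metric(table, list(atlas24.labels))
        per_subject_means = table.groupby("subject")["value"].mean()
        assert full[full["group"] == "A"]["mean"].item() == pytest.approx(per_subject_means["s1"])
        single = fc.roi_subset_metric(table, [atlas24.labels[0]])
        expected = table[(table["subject"] == "s1") & (table["node"] == atlas24.labels[0])]["value"].item()
        assert single[single["group"] == "A"]["mean"].item() == pytest.approx(expected)
        with pytest.raises(ValueError, match="empty"):
            fc.roi_subset_metric(table, [])
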