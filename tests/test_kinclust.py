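import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from demekin.kinclust import (
    ClusteringError,
    ClusterSupport,
    Dendrogram,
    DistanceMatrix,
    build_distance_matrix,
    diet_cluster_table,
    fisher_exact_rxc,
    leave_one_out_recluster,
    multiscale_bootstrap_au,
    relatedness_dendrogram,
    significant_clusters,
    upgma,
)


def naive_upgma(ids, d):
    """Brute-force O(n^3) average-linkage reference; heights = distance / 2."""
    d = d.astype(float).copy()
    order = np.argsort(ids)
    ids = [ids[i] for i in order]
    d = d[np.ix_(order, order)]
    clusters = {i: ([i], 1) for i in range(len(ids))}  # node -> (members, size)
    active = {i: i for i in range(len(ids))}  # cluster -> matrix row
    dist = {frozenset((a, b)): d[a, b] for a, b in itertools.combinations(range(len(ids)), 2)}
    merges = []
    nxt = len(ids)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((dist[frozenset((a, b))], a, b) for a, b in itertools.combinations(keys, 2)),
        )
        w, a, b = best
        na, nb = clusters[a][1], clusters[b][1]
        merges.append((a, b, w / 2.0, na + nb))
        for c in keys:
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            dist[frozenset((nxt, c))] = (na * dac + nb * dbc) / (na + nb)
        dist.pop(frozenset((a, b)))
        clusters[nxt] = (clusters[a][0] + clusters[b][0], na + nb)
        del clusters[a], clusters[b]
        nxt += 1
    return ids, merges


def _pairs_frame(ids, rxy):
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        rows.append({"id_x": ids[i], "id_y": ids[j], "r_xy": rxy[i, j]})
    return pd.DataFrame(rows)


def _two_family_pairs(bridge=False):
    """Two 4-member families (r=0.5 within, 0 across); optional bridge."""
    ids = [f"a{k}" for k in range(4)] + [f"b{k}" for k in range(4)]
    n = len(ids)
    r = np.zeros((n, n))
    r[:4, :4] = 0.5
    r[4:, 4:] = 0.5
    np.fill_diagonal(r, 1.0)
    if bridge:
        ids = ids + ["z"]
        r2 = np.zeros((n + 1, n + 1))
        r2[:n, :n] = r
        r2[n, 0] = r2[0, n] = 0.5
        r2[n, 4] = r2[4, n] = 0.5
        np.fill_diagonal(r2, 1.0)
        r = r2
    return _pairs_frame(ids, r)


class TestDistanceMatrix:
    def test_construction_and_clamping(self):
        pairs = pd.DataFrame(
            [
                {"id_x": "a", "id_y": "b", "r_xy": 1.0},
                {"id_x": "a", "id_y": "c", "r_xy": -0.1},
                {"id_x": "b", "id_y": "c", "r_xy": 1.2},
            ]
        )
        dm = build_distance_matrix(pairs)
        assert dm.ids == ["a", "b", "c"]
        i = {n: k for k, n in enumerate(dm.ids)}
        assert dm.matrix[i["a"], i["b"]] == 0.0  # duplicated pair
        assert dm.matrix[i["a"], i["c"]] == 1.0  # unrelated, clamped
        assert dm.matrix[i["b"], i["c"]] == 0.0  # r > 1 clamped

    def test_block_structure(self):
        pairs = _two_family_pairs()
        dm = build_distance_matrix(pairs)
        m = dm.matrix
        within = m[:4, :4][np.triu_indices(4, 1)]
        across = m[:4, 4:]
        assert np.all(within == 0.5) and np.all(across == 1.0)

    def test_missing_dyad_raises(self):
        pairs = pd.DataFrame(
            [
                {"id_x": "a", "id_y": "b", "r_xy": 0.5},
                {"id_x": "a", "id_y": "c", "r_xy": 0.5},
            ]
        )
        with pytest.raises(ClusteringError, match="missing dyads"):
            build_distance_matrix(pairs)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], matrix=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestUPGMA:
    def test_hand_computed_example(self):
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma(DistanceMatrix(ids=["a", "b", "c"], matrix=d))
        np.testing.assert_allclose(tree.node_heights(), [0.5, 2.0])
        assert tree.cluster_leafsets()[0] == frozenset({"a", "b"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        d = rng.uniform(0.1, 2.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"x{k}" for k in range(n)]
        tree = upgma(DistanceMatrix(ids=ids, matrix=d))
        oracle_ids, merges = naive_upgma(ids, d)
        np.testing.assert_allclose(
            tree.node_heights(), [m[2] for m in merges], rtol=1e-10
        )
        # leaf partitions agree merge by merge
        oracle_sets = []
        store = {i: frozenset([oracle_ids[i]]) for i in range(n)}
        for k, (a, b, _, _) in enumerate(merges):
            store[n + k] = store[a] | store[b]
            oracle_sets.append(store[n + k])
        assert tree.cluster_leafsets() == oracle_sets

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        n = 8
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"x{k}" for k in range(n)]
        t1 = upgma(DistanceMatrix(ids=ids, matrix=d))
        perm = rng.permutation(n)
        t2 = upgma(
            DistanceMatrix(ids=[ids[i] for i in perm], matrix=d[np.ix_(perm, perm)])
        )
        assert t1.to_newick() == t2.to_newick()

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_ultrametric(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = rng.uniform(0.0, 3.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma(DistanceMatrix(ids=[f"x{k}" for k in range(n)], matrix=d))
        assert tree.is_ultrametric()

    def test_too_few_leaves(self):
        with pytest.raises(ClusteringError):
            upgma(DistanceMatrix(ids=["a"], matrix=np.zeros((1, 1))))


class TestMultiscaleBootstrap:
    def test_perfect_clusters_reach_au_one(self):
        rng = np.random.default_rng(0)
        # two tight blobs in feature space, 30 features
        profiles = np.concatenate(
            [rng.normal(0, 0.05, (30, 4)), rng.normal(5, 0.05, (30, 4))], axis=1
        )
        ids = [f"s{k}" for k in range(8)]
        tree, support = multiscale_bootstrap_au(profiles, ids, nboot=1000, seed=1)
        leafsets = tree.cluster_leafsets()
        for block in (frozenset(ids[:4]), frozenset(ids[4:])):
            node = leafsets.index(block)
            au = support.table.set_index("node").loc[node, "au"]
            assert au >= 1 - 1e-3

    def test_single_scale_falls_back_to_bp(self):
        rng = np.random.default_rng(2)
        profiles = rng.normal(size=(20, 5))
        with pytest.warns(UserWarning, match="single bootstrap scale"):
            _, support = multiscale_bootstrap_au(
                profiles, list("abcde"), nboot=200, scales=(1.0,), seed=3
            )
        assert support.table["degenerate"].all()

    def test_au_in_unit_interval_and_reproducible(self):
        rng = np.random.default_rng(4)
        profiles = rng.normal(size=(25, 6))
        ids = list("abcdef")
        _, s1 = multiscale_bootstrap_au(profiles, ids, nboot=200, seed=9)
        _, s2 = multiscale_bootstrap_au(profiles, ids, nboot=200, seed=9)
        assert np.all((s1.table["au"] >= 0) & (s1.table["au"] <= 1))
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_nboot_floor(self):
        with pytest.raises(ClusteringError):
            multiscale_bootstrap_au(np.zeros((10, 3)), list("abc"), nboot=10)


class TestSignificantClusters:
    def _tree(self):
        pairs = _two_family_pairs()
        dm = build_distance_matrix(pairs)
        return upgma(dm)

    def _support(self, tree, au_values):
        table = pd.DataFrame(
            {"node": range(tree.n_leaves - 1), "au": au_values}
        )
        return ClusterSupport(table=table, scales=[1.0], nboot=100)

    def test_all_significant_yields_root_children(self):
        tree = self._tree()
        support = self._support(tree, [1.0] * (tree.n_leaves - 1))
        clusters, unassigned = significant_clusters(tree, support)
        assert len(clusters) == 2
        assert {frozenset(c["members"]) for c in clusters} == {
            frozenset(f"a{k}" for k in range(4)),
            frozenset(f"b{k}" for k in range(4)),
        }
        assert unassigned == []

    def test_none_significant(self):
        tree = self._tree()
        support = self._support(tree, [0.5] * (tree.n_leaves - 1))
        clusters, unassigned = significant_clusters(tree, support)
        assert clusters == []
        assert unassigned == sorted(tree.ids)

    def test_three_deme_simulation_recovers_demes(self, small_cohort):
        from demekin.genio import estimate_allele_frequencies
        from demekin.relatedness import pairwise_relatedness
        from demekin.simulate import (
            SimConfig,
            simulate_cohort,
            simulate_genotype_likelihoods,
        )

        cfg = SimConfig(seed=3, deme_sizes=[8, 8, 8], n_generations=2,
                        n_sites=400, divergence_fst=0.15, migration_rate=0.0)
        _, tg, _, truth = simulate_cohort(cfg)
        gl = simulate_genotype_likelihoods(tg, cfg)
        pairs = pairwise_relatedness(
            gl, estimate_allele_frequencies(gl), mode="k3", n_restarts=0
        )
        tree, support = relatedness_dendrogram(pairs, nboot=500, seed=1)
        leafsets = tree.cluster_leafsets()
        au = support.au()
        for deme in range(3):
            members = frozenset(i for i, d in truth.deme.items() if d == deme)
            node = leafsets.index(members)
            assert au[node] > 0.95


class TestFisherExact:
    def test_worked_2x2(self):
        assert fisher_exact_rxc([[3, 1], [1, 3]]) == pytest.approx(0.485714285714)

    def test_zero_row_gives_one(self):
        assert fisher_exact_rxc([[0, 0], [2, 3]]) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_on_2x2(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 8, size=(2, 2))
        if t.sum() == 0:
            t[0, 0] = 1
        assert fisher_exact_rxc(t) == pytest.approx(fisher_exact(t)[1], rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_2x3(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = rng.integers(0, 4, size=(2, 3))
        while t.sum() < 2 or t.sum() > 20:
            t = rng.integers(0, 4, size=(2, 3))
        # independent oracle: enumerate all 2x3 tables by brute force over
        # the first row, margins fixed
        from math import comb

        r = t.sum(axis=1)
        c = t.sum(axis=0)
        n = t.sum()

        def prob(tab):
            num = 1.0
            for j in range(3):
                num *= comb(int(c[j]), int(tab[j]))
            return num * comb(int(r[1]) + 0, 0) / comb(int(n), int(r[0])) * 1.0

        obs_p = prob(t[0])
        total = 0.0
        for x in range(int(min(r[0], c[0])) + 1):
            for y in range(int(min(r[0] - x, c[1])) + 1):
                z = int(r[0]) - x - y
                if 0 <= z <= c[2]:
                    p = prob([x, y, z])
                    if p <= obs_p * (1 + 1e-9):
                        total += p
        assert fisher_exact_rxc(t) == pytest.approx(total, rel=1e-7)

    @given(st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 5, size=(3, 3))
        if t.sum() == 0:
            t[1, 1] = 2
        p = fisher_exact_rxc(t)
        assert 0 < p <= 1
        assert fisher_exact_rxc(t[::-1]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_rxc(t[:, ::-1]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_rxc(t.T) == pytest.approx(p, rel=1e-9)

    def test_enumeration_bound(self):
        big = np.ones((6, 6), dtype=int)
        with pytest.raises(ValueError, match="mc=True"):
            fisher_exact_rxc(big)

    def test_monte_carlo_mode_close_to_exact(self):
        t = [[4, 1, 2], [1, 5, 1]]
        exact = fisher_exact_rxc(t)
        mc = fisher_exact_rxc(t, mc=True, n_mc=20000, seed=0)
        assert mc == pytest.approx(exact, abs=0.02)


class TestLeaveOneOut:
    def test_unknown_id(self):
        with pytest.raises(ClusteringError, match="unknown"):
            leave_one_out_recluster(_two_family_pairs(), "zzz", nboot=100)

    def test_too_small(self):
        pairs = pd.DataFrame([{"id_x": "a", "id_y": "b", "r_xy": 0.5}])
        with pytest.raises(ClusteringError):
            leave_one_out_recluster(pairs, "a", nboot=100)

    def test_dropping_bridge_restores_families(self):
        res = leave_one_out_recluster(_two_family_pairs(bridge=True), "z", nboot=300, seed=2)
        # without the bridging individual the two families are cleanly split
        assert res["n_clusters_reduced"] == 2
        sets = {frozenset(c["members"]) for c in res["clusters"]}
        assert frozenset(f"a{k}" for k in range(4)) in sets
        assert frozenset(f"b{k}" for k in range(4)) in sets

    def test_dropping_outsider_keeps_memberships(self):
        pairs = _two_family_pairs()
        full_tree, full_support = relatedness_dendrogram(pairs, nboot=300, seed=4)
        full_clusters, _ = significant_clusters(full_tree, full_support)
        res = leave_one_out_recluster(pairs, "b3", nboot=300, seed=4)
        kept = {frozenset(c["members"]) - {"b3"} for c in full_clusters}
        got = {frozenset(c["members"]) for c in res["clusters"]}
        assert frozenset(f"a{k}" for k in range(4)) in got


class TestDietTable:
    def test_counts_and_unknown_mask(self):
        clusters = [
            {"node": 0, "members": ["a", "b", "c"]},
            {"node": 1, "members": ["d", "e"]},
        ]
        diet = {"a": "fish", "b": "fish", "c": "unknown", "d": "mixed", "e": "fish"}
        tab = diet_cluster_table(diet, clusters)
        assert tab.loc["fish", "cluster0"] == 2
        assert tab.loc["mixed", "cluster1"] == 1
        assert tab.to_numpy().sum() == 4  # the unknown individual is masked
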