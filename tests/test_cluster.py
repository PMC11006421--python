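"""Clustering arm: normalisation, graph construction, community detection,
marker ranking, signature selection, SOM and consensus metaclustering."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import flniche as fl


def df(rows, index=None, columns=None):
    return pd.DataFrame(rows, index=index, columns=columns, dtype=float)


class TestNormalize:
    def test_arithmetic(self):
        m = pd.DataFrame([[10, 10, 0]], index=["c1"], columns=["g1", "g2", "g3"])
        out = fl.normalize_log1p(m, scale=1e4)
        assert out.loc["c1", "g1"] == pytest.approx(np.log1p(5000))
        assert out.loc["c1", "g3"] == 0.0

    def test_zero_cell_dropped_with_warning(self, caplog):
        m = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"], columns=["g1", "g2"])
        with caplog.at_level("WARNING"):
            out = fl.normalize_log1p(m)
        assert list(out.index) == ["a"]
        assert "zero total" in caplog.text

    def test_all_equal_cells_identical(self):
        m = pd.DataFrame(np.full((4, 3), 7), columns=list("abc"))
        out = fl.normalize_log1p(m)
        assert np.allclose(out.to_numpy(), out.to_numpy()[0])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            fl.normalize_log1p(pd.DataFrame())


class TestKnnGraph:
    def test_two_points(self):
        feats = df([[0.0], [1.0]], index=["a", "b"])
        g = fl.build_knn_graph(feats, k=1)
        assert list(g.edges(data="weight")) == [("a", "b", 1.0)]

    def test_matches_bruteforce_1d(self):
        pos = [0.0, 1.0, 2.0, 10.0, 11.0]
        ids = [f"p{i}" for i in range(5)]
        feats = df([[p] for p in pos], index=ids)
        k = 2
        g = fl.build_knn_graph(feats, k=k)
        # O(n^2) oracle: neighbor sets by sorting distances
        D = np.abs(np.subtract.outer(pos, pos)).astype(float)
        np.fill_diagonal(D, np.inf)
        nbr = {i: set(np.argsort(D[i], kind="stable")[:k]) | {i} for i in range(5)}
        expected = set()
        for i in range(5):
            for j in nbr[i] - {i}:
                expected.add(tuple(sorted((i, j))))
        expected_edges = {
            (ids[i], ids[j]) for i, j in expected
            if len(nbr[i] & nbr[j]) > 0  # zero-Jaccard edges dropped
        }
        assert set(map(tuple, map(sorted, g.edges))) == expected_edges
        for u, v, w in g.edges(data="weight"):
            i, j = ids.index(u), ids.index(v)
            assert w == pytest.approx(len(nbr[i] & nbr[j]) / len(nbr[i] | nbr[j]))

    def test_duplicate_points_deterministic(self):
        feats = df([[0.0], [0.0], [0.0], [5.0]], index=list("abcd"))
        g1 = fl.build_knn_graph(feats, k=1)
        g2 = fl.build_knn_graph(feats, k=1)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_errors(self):
        feats = df([[0.0], [1.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            fl.build_knn_graph(feats, k=2)
        bad = df([[np.nan], [1.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="NaN"):
            fl.build_knn_graph(bad, k=1)


def _clique(ids):
    g = nx.Graph()
    for u, v in itertools.combinations(ids, 2):
        g.add_edge(u, v, weight=1.0)
    return g


class TestCommunityDetect:
    def test_two_disconnected_cliques(self):
        g = nx.union(_clique(list("abcde")), _clique(list("fghij")))
        labels = fl.community_detect(g, seed=0)
        assert labels.nunique() == 2
        assert labels["a"] == labels["e"] and labels["f"] == labels["j"]
        assert labels["a"] != labels["f"]

    def test_barbell_matches_exhaustive_modularity_optimum(self):
        # two 4-cliques joined by one edge; brute force over all partitions
        g = _clique(list("abcd"))
        g = nx.union(g, _clique(list("efgh")))
        g.add_edge("d", "e", weight=1.0)
        nodes = sorted(g.nodes)

        def partitions(collection):
            if len(collection) == 1:
                yield [collection]
                return
            first, rest = collection[0], collection[1:]
            for smaller in partitions(rest):
                for i, subset in enumerate(smaller):
                    yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
                yield [[first]] + smaller

        best = max(
            partitions(nodes),
            key=lambda p: nx.community.modularity(g, [set(s) for s in p]),
        )
        best_sets = {frozenset(s) for s in best}
        labels = fl.community_detect(g, seed=0)
        got = {frozenset(labels.index[labels == c]) for c in labels.unique()}
        assert got == best_sets

    def test_small_resolution_single_community(self):
        g = nx.union(_clique(list("abc")), _clique(list("def")))
        g.add_edge("c", "d", weight=0.1)
        labels = fl.community_detect(g, resolution=1e-6, seed=0)
        assert labels.nunique() == 1

    def test_edgeless_graph_singletons(self, caplog):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with caplog.at_level("WARNING"):
            labels = fl.community_detect(g, seed=0)
        assert labels.nunique() == 3
        assert "no edges" in caplog.text

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        l1 = fl.community_detect(g, seed=5)
        l2 = fl.community_detect(g, seed=5)
        pd.testing.assert_series_equal(l1, l2)

    def test_modularity_not_below_singletons(self):
        g = nx.gnp_random_graph(30, 0.2, seed=1)
        nx.set_edge_attributes(g, 1.0, "weight")
        labels = fl.community_detect(g, seed=0)
        parts = [set(labels.index[labels == c]) for c in labels.unique()]
        single = [{n} for n in g.nodes]
        assert nx.community.modularity(g, parts) >= nx.community.modularity(g, single)


class TestRankGenes:
    @staticmethod
    def _toy():
        vals = pd.DataFrame({
            "g_sep": [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],
            "g_const": [2.0] * 6,
        }, index=[f"c{i}" for i in range(6)])
        labels = pd.Series(["hi"] * 3 + ["lo"] * 3, index=vals.index)
        return vals, labels

    def test_constant_gene(self):
        vals, labels = self._toy()
        t = fl.rank_genes(vals, labels)
        row = t[(t["cluster"] == "hi") & (t["gene"] == "g_const")].iloc[0]
        assert row["pval"] == 1.0 and row["effect"] == 0.0

    def test_exact_p_matches_enumeration(self):
        vals, labels = self._toy()
        t = fl.rank_genes(vals, labels)
        row = t[(t["cluster"] == "hi") & (t["gene"] == "g_sep")].iloc[0]
        # enumeration oracle: all C(6,3) = 20 splits of the ranks
        obs_u = 9.0
        count = 0
        for combo in itertools.combinations(range(6), 3):
            ranks = np.array(combo) + 1
            u = ranks.sum() - 3 * 4 / 2
            if abs(u - 4.5) >= abs(obs_u - 4.5):
                count += 1
        assert row["statistic"] == pytest.approx(obs_u)
        assert row["pval"] == pytest.approx(count / 20)

    def test_bh_matches_stepup_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.9])
        # independent step-up oracle
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_i in range(m - 1, -1, -1):
            i = order[rank_i]
            running = min(running, p[i] * m / (rank_i + 1))
            adj[i] = running
        assert np.allclose(fl.bh_adjust(p), adj)
        # order preserved
        assert np.all(np.diff(fl.bh_adjust(p)[np.argsort(p)]) >= -1e-15)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(100, 200)),
                            index=[f"c{i}" for i in range(100)])
        vals.columns = [f"g{i}" for i in range(200)]
        labels = pd.Series(rng.choice(["a", "b"], size=100), index=vals.index)
        t = fl.rank_genes(vals, labels)
        p = t[t["cluster"] == "a"]["pval"].to_numpy()
        assert kstest(p, "uniform").pvalue > 0.01

    def test_single_cluster_error(self):
        vals = pd.DataFrame(np.ones((4, 2)), index=list("abcd"))
        labels = pd.Series(["x"] * 4, index=vals.index)
        with pytest.raises(ValueError):
            fl.rank_genes(vals, labels)


class TestSignatureScore:
    def test_identical_cells_score_zero(self):
        m = pd.DataFrame(np.full((3, 2), 4.0), index=list("abc"), columns=["g1", "g2"])
        s = fl.score_signature(m, ["g1", "g2"])
        assert np.allclose(s.to_numpy(), 0.0)

    def test_max_cell_has_max_score(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.uniform(0, 1, (10, 4)), index=[f"c{i}" for i in range(10)])
        m.columns = list("wxyz")
        m.loc["c3"] = 2.0
        s = fl.score_signature(m, list("wxyz"))
        assert s.idxmax() == "c3"

    def test_hand_arithmetic(self):
        m = pd.DataFrame({"g1": [0.0, 1.0, 2.0], "g2": [2.0, 2.0, 2.0]}, index=list("abc"))
        s = fl.score_signature(m, ["g1", "g2"])
        # g1 z-scores: (-1.2247, 0, 1.2247); g2 constant -> 0
        z = (np.array([0, 1, 2]) - 1.0) / np.std([0, 1, 2])
        assert np.allclose(s.to_numpy(), z / 2)

    def test_missing_all_genes_error(self):
        m = pd.DataFrame({"g1": [0.0, 1.0]}, index=list("ab"))
        with pytest.raises(ValueError):
            fl.score_signature(m, ["nope"])


class TestSelectClusters:
    def test_identical_scores_positive_margin_errors(self):
        labels = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        scores = pd.Series([1.0] * 4, index=list("wxyz"))
        with pytest.raises(ValueError, match="no clusters"):
            fl.select_clusters(labels, scores, margin=0.5)

    def test_planted_high_cluster_selected(self):
        labels = pd.Series(["hi"] * 3 + ["lo"] * 3, index=[f"c{i}" for i in range(6)])
        scores = pd.Series([2.0] * 3 + [0.0] * 3, index=labels.index)
        ids, report = fl.select_clusters(labels, scores, margin=0.5)
        assert set(ids) == {"c0", "c1", "c2"}
        assert report.loc["hi", "kept"] and not report.loc["lo", "kept"]

    def test_very_negative_margin_keeps_all(self):
        labels = pd.Series(["a", "b"], index=["x", "y"])
        scores = pd.Series([0.0, 5.0], index=["x", "y"])
        ids, _ = fl.select_clusters(labels, scores, margin=-1e9)
        assert set(ids) == {"x", "y"}


class TestIterativeRefine:
    def test_default_has_three_rounds(self):
        assert len(fl.default_rounds()) == 3

    def test_decoys_removed_and_truth_recovered(self):
        pops = {"mac1": 50, "mac2": 50, "mono": 50, "gran": 50}
        mac_shared = [f"Mac{j}" for j in range(10)]
        sigs = {
            "mac1": mac_shared + [f"M1_{j}" for j in range(10)],
            "mac2": mac_shared + [f"M2_{j}" for j in range(10)],
            "mono": [f"Mo{j}" for j in range(15)],
            "gran": [f"Gr{j}" for j in range(15)],
        }
        cfg = fl.SimConfig(seed=8, populations=pops, population_signatures=sigs,
                           progenitor_bridge=None, n_genes=400)
        ex, truth = fl.gen_expression(cfg)
        # decisive signature selection in round 1; later rounds re-cluster the
        # retained macrophages with a permissive margin
        rounds = [fl.RefineRound(tuple(mac_shared), margin=0.2),
                  fl.RefineRound(tuple(mac_shared), margin=-0.5),
                  fl.RefineRound(tuple(mac_shared), margin=-0.5)]
        res = fl.iterative_refine(ex, rounds, fl.RefineParams(seed=0))
        kept_truth = truth.true_labels.loc[res.labels.index]
        assert set(kept_truth.unique()) <= {"mac1", "mac2"}
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(kept_truth, res.labels) >= 0.9

    def test_emptying_round_named_in_error(self):
        pops = {"a": 30, "b": 30}
        sigs = {"a": ["S1"], "b": ["S2"]}
        cfg = fl.SimConfig(seed=0, populations=pops, population_signatures=sigs,
                           progenitor_bridge=None, n_genes=50)
        ex, _ = fl.gen_expression(cfg)
        rounds = [fl.RefineRound(("S1",), margin=1e9)]
        with pytest.raises(ValueError, match="round 1"):
            fl.iterative_refine(ex, rounds)


class TestConnectivity:
    def test_disconnected_pairs_zero(self):
        g = nx.union(_clique(list("abc")), _clique(list("def")))
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        conn = fl.cluster_graph_connectivity(g, labels)
        assert conn.loc["x", "y"] == 0.0 and conn.loc["x", "x"] == 0.0

    def test_complete_bipartite_saturates(self):
        g = nx.complete_bipartite_graph(3, 3)
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=range(6))
        conn = fl.cluster_graph_connectivity(g, labels)
        assert conn.loc["x", "y"] == 1.0

    def test_hand_arithmetic(self):
        # X={a,b}: a-b; Y={c,d}: c-d; inter: a-c.  E=3, D_X=3, D_Y=3, e=1
        g = nx.Graph([("a", "b"), ("c", "d"), ("a", "c")])
        labels = pd.Series(["X", "X", "Y", "Y"], index=list("abcd"))
        conn = fl.cluster_graph_connectivity(g, labels)
        assert conn.loc["X", "Y"] == pytest.approx(min(1.0, 1 / (3 * 3 / (2 * 3))))
        assert conn.loc["Y", "X"] == conn.loc["X", "Y"]

    def test_id_mismatch_error(self):
        g = nx.Graph([("a", "b")])
        labels = pd.Series(["x"], index=["a"])
        with pytest.raises(ValueError):
            fl.cluster_graph_connectivity(g, labels)


class TestSOM:
    def test_single_node_learns_mean_and_qe_closed_form(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 3)))
        model, assign = fl.som_fit(X, grid=(1, 1), epochs=1, seed=0)
        assert np.allclose(model.codebook[0], X.mean().to_numpy())
        expected_qe = float(((X - X.mean()) ** 2).sum(axis=1).mean())
        assert model.qe_history[-1] == pytest.approx(expected_qe)

    def test_two_clouds_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.05, size=(40, 2))
        b = rng.normal(5, 0.05, size=(40, 2))
        X = pd.DataFrame(np.vstack([a, b]))
        model, assign = fl.som_fit(X, grid=(1, 2), epochs=15, seed=0)
        means = sorted(model.codebook[:, 0])
        assert abs(means[0] - 0.0) < 0.1 and abs(means[1] - 5.0) < 0.1
        assert assign.iloc[:40].nunique() == 1 and assign.iloc[40:].nunique() == 1
        assert assign.iloc[0] != assign.iloc[-1]

    def test_zero_epochs_is_seeded_init(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        model, _ = fl.som_fit(X, grid=(2, 2), epochs=0, seed=0)
        rows = {tuple(r) for r in X.to_numpy()}
        assert all(tuple(c) in rows for c in model.codebook)
        assert model.qe_history == []

    def test_qe_nonincreasing(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(200, 4)))
        model, _ = fl.som_fit(X, grid=(4, 4), epochs=20, seed=0)
        qe = model.qe_history
        assert all(b <= a * (1 + 1e-9) for a, b in zip(qe, qe[1:]))

    def test_too_many_nodes_error(self):
        X = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            fl.som_fit(X, grid=(2, 2), epochs=1, seed=0)


class TestConsensus:
    @staticmethod
    def _three_groups():
        rng = np.random.default_rng(0)
        return np.vstack([
            rng.normal(0, 0.1, (6, 2)),
            rng.normal(5, 0.1, (6, 2)),
            rng.normal(10, 0.1, (6, 2)),
        ])

    def test_k_equals_nodes_singletons(self):
        cb = self._three_groups()
        labels = fl.consensus_metacluster(cb, K=len(cb), seed=0)
        assert len(set(labels)) == len(cb)

    def test_three_groups_exact(self):
        from sklearn.metrics import adjusted_rand_score

        cb = self._three_groups()
        truth = [0] * 6 + [1] * 6 + [2] * 6
        labels = fl.consensus_metacluster(cb, K=3, resamples=100, subsample_frac=0.8, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_degenerate_consensus_is_plain_cut(self):
        from scipy.cluster.hierarchy import fcluster, linkage

        cb = self._three_groups()
        labels = fl.consensus_metacluster(cb, K=3, resamples=1, subsample_frac=1.0, seed=0)
        plain = fcluster(linkage(cb, method="average", metric="euclidean"), 3, criterion="maxclust")
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(plain, labels) == 1.0

    def test_k_too_large_error(self):
        with pytest.raises(ValueError):
            fl.consensus_metacluster(np.zeros((4, 2)), K=5)
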