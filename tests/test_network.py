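from collections import deque

import numpy as np
import pandas as pd
import pytest

from aecg.exceptions import NetworkError
from aecg.io import CohortTable
from aecg.network import (CorrelationNetwork, certainty_index, correlation_network,
                          network_metrics, pairwise_pearson, patient_similarity,
                          rewiring_scores)

import networkx as nx


def _net_from_edges(nodes, edges):
    """Build a CorrelationNetwork directly from (u, v, weight) triples."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, n_obs=100, p=1e-9, significant=True)
    return CorrelationNetwork(g, 0.45, 82, 1.2e-6)


def _frame(n, seed=0, m=8):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(rng.normal(size=(n, m)),
                         columns=[f"v{i}" for i in range(m)])
    frame.index = pd.Index([f"p{i}" for i in range(n)], name="subject_id")
    return frame


class TestCorrelationNetwork:
    def test_exact_linear_pair(self):
        frame = _frame(100, seed=1)
        frame["v1"] = 2.0 * frame["v0"]
        net = correlation_network(frame)
        assert net.graph.has_edge("v0", "v1")
        assert net.graph.edges["v0", "v1"]["weight"] == pytest.approx(1.0)
        assert net.graph.edges["v0", "v1"]["significant"]

    def test_independent_variables_no_edges(self):
        net = correlation_network(_frame(300, seed=2, m=10))
        assert net.n_edges == 0

    def test_low_support_pair_never_significant(self):
        frame = _frame(100, seed=3)
        frame["v1"] = frame["v0"] * 1.5
        frame.loc[frame.index[50:], ["v1"]] = np.nan  # only 50 paired obs
        net = correlation_network(frame, n_min=82)
        assert net.graph.has_edge("v0", "v1")
        assert net.graph.edges["v0", "v1"]["n_obs"] == 50
        assert not net.graph.edges["v0", "v1"]["significant"]

    def test_affine_rescaling_invariance(self):
        frame = _frame(80, seed=4)
        frame["v1"] = frame["v0"] + 0.3 * frame["v2"]
        net1 = correlation_network(frame)
        rescaled = frame.copy()
        rescaled["v1"] = -5.0 + 1000.0 * rescaled["v1"]
        net2 = correlation_network(rescaled)
        assert set(net1.graph.edges) == set(net2.graph.edges)
        for u, v in net1.graph.edges:
            assert abs(net1.graph.edges[u, v]["weight"]) == pytest.approx(
                abs(net2.graph.edges[u, v]["weight"]))

    def test_all_missing_column_kept_isolated(self):
        frame = _frame(50, seed=5)
        frame["empty"] = np.nan
        net = correlation_network(frame)
        assert "empty" in net.nodes
        assert net.graph.degree["empty"] == 0
        assert net.graph.nodes["empty"]["all_missing"]

    def test_too_few_patients_rejected(self):
        with pytest.raises(NetworkError):
            correlation_network(_frame(2))

    def test_pairwise_p_values_match_scipy(self):
        from scipy.stats import pearsonr
        frame = _frame(40, seed=6, m=4)
        r, n, p = pairwise_pearson(frame)
        expect_r, expect_p = pearsonr(frame["v0"], frame["v1"])
        assert r.loc["v0", "v1"] == pytest.approx(expect_r)
        assert p.loc["v0", "v1"] == pytest.approx(expect_p, rel=1e-6)


class TestNetworkMetrics:
    def test_path_graph(self):
        net = _net_from_edges("ABC", [("A", "B", 0.9), ("B", "C", 0.8)])
        m = network_metrics(net)
        assert m.betweenness["B"] == pytest.approx(1.0)
        assert m.betweenness["A"] == 0.0
        assert sorted(m.path_lengths.values()) == [1, 1, 2]

    def test_complete_graph_k4(self):
        nodes = "ABCD"
        edges = [(u, v, 0.9) for i, u in enumerate(nodes)
                 for v in nodes[i + 1:]]
        m = network_metrics(_net_from_edges(nodes, edges))
        assert all(b == 0.0 for b in m.betweenness.values())
        assert set(m.path_lengths.values()) == {1}

    def test_disconnected_pairs_counted(self):
        net = _net_from_edges("ABCD", [("A", "B", 0.9)])
        m = network_metrics(net)
        assert m.n_disconnected_pairs == 5
        assert m.path_lengths == {("A", "B"): 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_path_lengths_match_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(10)]
        edges = [(u, v, 0.9) for i, u in enumerate(nodes)
                 for v in nodes[i + 1:] if rng.random() < 0.25]
        net = _net_from_edges(nodes, edges)
        adj = {u: set() for u in nodes}
        for u, v, _ in edges:
            adj[u].add(v)
            adj[v].add(u)

        def bfs(start):
            dist = {start: 0}
            queue = deque([start])
            while queue:
                u = queue.popleft()
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        queue.append(w)
            return dist

        m = network_metrics(net)
        for i, u in enumerate(sorted(nodes)):
            dist = bfs(u)
            for v in sorted(nodes)[i + 1:]:
                if v in dist:
                    assert m.path_lengths[(u, v)] == dist[v]
                else:
                    assert (u, v) not in m.path_lengths


class TestRewiring:
    def test_identical_networks_score_zero(self):
        edges = [("A", "B", 0.9), ("B", "C", -0.6)]
        a = _net_from_edges("ABC", edges)
        b = _net_from_edges("ABC", edges)
        assert all(s == pytest.approx(0.0) for s in rewiring_scores(a, b).values())

    def test_disjoint_neighbourhoods_score_one(self):
        a = _net_from_edges("ABC", [("A", "B", 0.9)])
        b = _net_from_edges("ABC", [("A", "C", 0.9)])
        scores = rewiring_scores(a, b)
        assert scores["A"] == pytest.approx(1.0)
        assert scores["B"] == pytest.approx(1.0)  # isolated in b only

    def test_hand_computed_three_node_example(self):
        a = _net_from_edges("ABC", [("A", "B", 0.8), ("A", "C", 0.6)])
        b = _net_from_edges("ABC", [("A", "B", 0.8)])
        # A: cos = 0.8*0.8 / (sqrt(.64+.36)*0.8) = 0.8 -> score 0.2
        assert rewiring_scores(a, b)["A"] == pytest.approx(0.2)

    def test_mismatched_nodes_rejected(self):
        a = _net_from_edges("AB", [("A", "B", 0.9)])
        b = _net_from_edges("ABC", [("A", "B", 0.9)])
        with pytest.raises(NetworkError):
            rewiring_scores(a, b)


class TestCertaintyIndex:
    def test_full_and_empty(self):
        full = _net_from_edges("ABCD", [("A", "B", 0.9), ("C", "D", 0.8)])
        assert certainty_index(full, 4) == pytest.approx(100.0)
        empty = _net_from_edges("ABCD", [])
        assert certainty_index(empty, 4) == 0.0

    def test_matches_flag_count(self):
        net = _net_from_edges("ABCDE", [("A", "B", 0.9)])
        net.graph.add_edge("C", "D", weight=0.7, n_obs=10, p=0.5, significant=False)
        involved = {n for u, v, d in net.graph.edges(data=True)
                    if d["significant"] for n in (u, v)}
        assert certainty_index(net, 5) == pytest.approx(100.0 * len(involved) / 5)

    def test_zero_variables_rejected(self):
        with pytest.raises(NetworkError):
            certainty_index(_net_from_edges("AB", []), 0)


class TestPatientSimilarity:
    def _labelled_frame(self, x, labels):
        frame = pd.DataFrame(x, columns=[f"f{i}" for i in range(x.shape[1])])
        frame["event"] = labels
        frame.index = pd.Index([f"p{i}" for i in range(len(frame))],
                               name="subject_id")
        return frame

    def test_duplicate_patients_fully_similar(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=6)
        x = np.vstack([row, row, rng.normal(size=6), rng.normal(size=6)])
        res = patient_similarity(self._labelled_frame(x, [1, 1, 0, 0]), "event",
                                 n_permutations=10)
        assert res.similarity.matrix.iloc[0, 1] == pytest.approx(1.0)

    def test_orthogonal_patients_zero_similarity(self):
        x = np.zeros((4, 4))
        x[0, 0] = x[1, 1] = x[2, 2] = x[3, 3] = 1.0
        res = patient_similarity(self._labelled_frame(x, [1, 1, 0, 0]), "event",
                                 n_permutations=10)
        sim = res.similarity.matrix.to_numpy()
        # centering preserves orthogonality structure up to the shared mean
        assert abs(sim[0, 2]) < abs(sim[0, 0])

    def test_similarity_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        frame = self._labelled_frame(rng.normal(size=(12, 5)),
                                     rng.integers(0, 2, 12))
        res = patient_similarity(frame, "event", n_permutations=10)
        sim = res.similarity.matrix.to_numpy()
        np.testing.assert_allclose(sim, sim.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sim), 1.0)
        eig = np.linalg.eigvalsh(sim)
        assert eig.min() > -1e-8  # Gram structure

    @pytest.mark.parametrize("seed", range(10))
    def test_clusters_more_similar_within(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, (15, 10)) + 2.0
        b = rng.normal(0.0, 1.0, (15, 10)) - 2.0
        frame = self._labelled_frame(np.vstack([a, b]), [1] * 15 + [0] * 15)
        res = patient_similarity(frame, "event", n_permutations=50, rng=seed)
        assert res.median_within_event > res.median_between

    def test_permutation_p_detects_structure(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, (20, 8)) + 1.5
        b = rng.normal(0.0, 1.0, (20, 8)) - 1.5
        frame = self._labelled_frame(np.vstack([a, b]), [1] * 20 + [0] * 20)
        res = patient_similarity(frame, "event", n_permutations=200, rng=0)
        assert res.permutation_p < 0.05

    def test_all_missing_patient_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 4))
        frame = self._labelled_frame(x, [1, 1, 0, 0, 0])
        frame.iloc[2, :4] = np.nan
        with pytest.warns(UserWarning):
            res = patient_similarity(frame, "event", n_permutations=10)
        assert res.similarity.n_patients == 4


def test_subset_network_contract():
    # rebuilding on the non-event subset and the full cohort gives the two
    # networks the rewiring comparison consumes
    from aecg.simulate import CohortSimConfig, simulate_cohort
    table, _ = simulate_cohort(CohortSimConfig(seed=11))
    cols = [c for c in table.numeric_columns()
            if c not in ("event", "hf_event", "time_days", "hf_time_days")]
    full = correlation_network(table.data[cols])
    non_event = correlation_network(table.data.loc[table.data.event == 0, cols])
    scores = rewiring_scores(non_event, full)
    assert set(scores) == set(full.nodes)
    assert all(0.0 <= s <= 2.0 for s in scores.values())
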