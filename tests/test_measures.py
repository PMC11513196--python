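"""Network measures against closed forms and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

import stabnet as sn
from stabnet.model import GGMResults, refit_support
from stabnet.measures import (
    classical_centralities,
    current_flow_closeness,
    degree_centrality,
    holdout_predictability,
    maximal_spanning_tree,
    predictability,
)

from conftest import standardized_sample


def results_from_weights(W: np.ndarray, labels=None) -> GGMResults:
    """Results object with a prescribed signed weighted adjacency (tests only)."""
    p = W.shape[0]
    labels = labels or [f"n{i:02d}" for i in range(p)]
    support = (np.abs(W) > 0).astype(int)
    np.fill_diagonal(support, 0)
    res = GGMResults(labels, np.eye(p), support)
    res.partial_corr = W + np.eye(p)
    return res


def random_weighted_graph(p, seed, density=0.6):
    rng = np.random.default_rng(seed)
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.1, 0.9) * rng.choice([-1, 1])
    return W


# ---------------------------------------------------------------------------
# predictability
# ---------------------------------------------------------------------------
class TestPredictability:
    def test_isolated_node_zero(self):
        theta = np.eye(3)
        theta[0, 1] = theta[1, 0] = -0.3
        res = GGMResults(["a", "b", "c"], theta, (np.abs(theta) > 0).astype(int) - np.eye(3, dtype=int))
        assert predictability(res)[2] == pytest.approx(0.0)

    def test_matches_least_squares_regression(self):
        """Chain model: implied R^2 equals nodewise OLS on a large sample."""
        spec = sn.make_precision(6, 0.4, (0.2, 0.4), seed=7)
        tab = standardized_sample(spec, 100000, seed=8)
        X = tab.values()
        res = refit_support(X, np.ones((6, 6), dtype=int) - np.eye(6, dtype=int))
        pr = predictability(res)
        for i in range(6):
            others = [j for j in range(6) if j != i]
            beta, *_ = np.linalg.lstsq(X[:, others], X[:, i], rcond=None)
            resid = X[:, i] - X[:, others] @ beta
            r2 = 100 * (1 - resid.var() / X[:, i].var())
            assert pr[i] == pytest.approx(r2, abs=0.5)

    def test_permutation_equivariance(self, fitted12):
        _, _, res = fitted12
        perm = np.random.default_rng(0).permutation(res.p)
        permuted = GGMResults(
            [res.node_labels[i] for i in perm],
            res.theta[np.ix_(perm, perm)],
            res.support[np.ix_(perm, perm)],
        )
        assert np.allclose(predictability(permuted), predictability(res)[perm])
        assert np.allclose(degree_centrality(permuted), degree_centrality(res)[perm])
        assert np.allclose(
            current_flow_closeness(permuted), current_flow_closeness(res)[perm]
        )


class TestHoldoutPredictability:
    def test_close_to_training_value_on_same_distribution(self):
        spec = sn.make_precision(8, 0.3, (0.2, 0.4), seed=9)
        train = standardized_sample(spec, 20000, seed=10)
        test = standardized_sample(spec, 20000, seed=11)
        res = refit_support(train, spec.true_support)
        tr = predictability(res)
        ho = holdout_predictability(res, test)
        assert np.max(np.abs(tr - ho)) < 3.0

    def test_permuted_test_column_destroys_signal(self):
        spec = sn.make_precision(5, 0.5, (0.3, 0.4), seed=12)
        train = standardized_sample(spec, 5000, seed=13)
        test = standardized_sample(spec, 5000, seed=14)
        res = refit_support(train, spec.true_support)
        connected = int(np.argmax(res.support.sum(1)))
        X = test.values().copy()
        X[:, connected] = np.random.default_rng(1).permutation(X[:, connected])
        ho = holdout_predictability(res, X)
        assert ho[connected] <= 2.0  # at or below zero up to noise

    def test_no_edge_node_nonpositive(self):
        theta = np.eye(3)
        theta[0, 1] = theta[1, 0] = -0.3
        res = GGMResults(["a", "b", "c"], theta,
                         (np.abs(theta) > 0).astype(int) - np.eye(3, dtype=int))
        X = np.random.default_rng(2).standard_normal((500, 3))
        assert holdout_predictability(res, X)[2] <= 0.0

    def test_label_mismatch_rejected(self, fitted12):
        _, table, res = fitted12
        import pandas as pd

        bad = sn.DataTable(
            pd.DataFrame(table.values(), columns=[f"x{i}" for i in range(12)]),
            {f"x{i}": "trait" for i in range(12)},
        )
        with pytest.raises(ValueError, match="do not match"):
            holdout_predictability(res, bad)


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------
class TestDegreeCentrality:
    def test_star_graph_closed_form(self):
        p = 11
        W = np.zeros((p, p))
        W[0, 1:] = W[1:, 0] = 0.3
        res = results_from_weights(W)
        deg = degree_centrality(res)
        assert deg[0] == pytest.approx(1.0)
        assert np.allclose(deg[1:], 1 / (p - 1))

    def test_isolated_node_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        assert degree_centrality(results_from_weights(W))[3] == 0.0


class TestCurrentFlowCloseness:
    def test_two_node_unit_edge(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 1.0
        vals = current_flow_closeness(results_from_weights(W))
        assert np.allclose(vals, [1.0, 1.0])  # R_eff = 1, (p-1)/sum = 1

    def test_path_center_exceeds_leaves(self):
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1.0
        vals = current_flow_closeness(results_from_weights(W))
        assert vals[1] > vals[0] and vals[2] > vals[3]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_pairwise_linear_system_oracle(self, seed):
        """Brute force: solve L x = e_s - e_t per pair for the resistance."""
        W = np.abs(random_weighted_graph(6, seed))
        G = nx.from_numpy_array(W)
        if not nx.is_connected(G):
            W = W + 0.05 * (np.ones((6, 6)) - np.eye(6))
        res = results_from_weights(W)
        vals = current_flow_closeness(res)
        A = np.abs(res.partial_corr) * res.support
        L = np.diag(A.sum(1)) - A
        oracle = np.zeros(6)
        for v in range(6):
            total = 0.0
            for t in range(6):
                if t == v:
                    continue
                rhs = np.zeros(6)
                rhs[v], rhs[t] = 1.0, -1.0
                x = np.linalg.lstsq(L, rhs, rcond=None)[0]
                total += x[v] - x[t]
            oracle[v] = 5.0 / total
        assert np.max(np.abs(vals - oracle)) < 1e-8

    def test_increases_with_incident_conductance(self):
        base = np.zeros((4, 4))
        base[0, 1] = base[1, 0] = 0.4
        base[1, 2] = base[2, 1] = 0.4
        base[2, 3] = base[3, 2] = 0.4
        v0 = current_flow_closeness(results_from_weights(base))
        boosted = base.copy()
        boosted[0, 1] = boosted[1, 0] = 0.8
        v1 = current_flow_closeness(results_from_weights(boosted))
        assert v1[0] > v0[0] and v1[1] > v0[1]


class TestClassicalCentralities:
    def test_star_betweenness(self):
        p = 6
        W = np.zeros((p, p))
        W[0, 1:] = W[1:, 0] = 0.5
        cc = classical_centralities(results_from_weights(W))
        assert cc["betweenness"][0] > 0
        assert np.allclose(cc["betweenness"][1:], 0.0)

    def test_path_closeness_ordering(self):
        p = 5
        W = np.zeros((p, p))
        for i in range(p - 1):
            W[i, i + 1] = W[i + 1, i] = 0.5
        cc = classical_centralities(results_from_weights(W))
        clo = cc["closeness"]
        assert clo[2] >= clo[1] >= clo[0]
        assert clo[2] >= clo[3] >= clo[4]

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_betweenness_matches_path_enumeration(self, seed):
        """5-node oracle: enumerate all simple paths, count shortest-path shares."""
        W = np.abs(random_weighted_graph(5, seed, density=0.7))
        W = W + 0.05 * (np.ones((5, 5)) - np.eye(5))  # ensure connected
        np.fill_diagonal(W, 0.0)
        res = results_from_weights(W)
        btw = classical_centralities(res)["betweenness"]
        D = np.where(W > 0, 1.0 / W, np.inf)
        oracle = np.zeros(5)
        for s, t in itertools.combinations(range(5), 2):
            best, paths = np.inf, []
            for k in range(5):
                for mid in itertools.permutations([m for m in range(5) if m not in (s, t)], k):
                    path = [s, *mid, t]
                    length = sum(D[path[i], path[i + 1]] for i in range(len(path) - 1))
                    if length < best - 1e-12:
                        best, paths = length, [path]
                    elif abs(length - best) <= 1e-12:
                        paths.append(path)
            for v in range(5):
                if v in (s, t):
                    continue
                oracle[v] += sum(v in p_ for p_ in paths) / len(paths)
        oracle /= (4 * 3) / 2  # normalization over pairs
        assert np.max(np.abs(btw - oracle)) < 1e-10


# ---------------------------------------------------------------------------
# maximal spanning tree
# ---------------------------------------------------------------------------
def all_spanning_trees_max_weight(W: np.ndarray) -> float:
    p = W.shape[0]
    edges = [(i, j, abs(W[i, j])) for i in range(p) for j in range(i + 1, p) if W[i, j] != 0]
    best = -np.inf
    for combo in itertools.combinations(edges, p - 1):
        G = nx.Graph()
        G.add_nodes_from(range(p))
        G.add_weighted_edges_from(combo)
        if nx.is_connected(G):
            best = max(best, sum(w for _, _, w in combo))
    return best


class TestMaximalSpanningTree:
    def test_triangle_drops_smallest_edge(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.4
        W[0, 2] = W[2, 0] = 0.3
        tree = maximal_spanning_tree(results_from_weights(W, ["a", "b", "c"]))
        assert tree.total_weight == pytest.approx(0.9)
        kept = {(u, v) for u, v, _ in tree.edges}
        assert kept == {("a", "b"), ("b", "c")}

    def test_tree_input_returned_unchanged(self):
        W = np.zeros((5, 5))
        for i in range(4):
            W[i, i + 1] = W[i + 1, i] = 0.2 + 0.1 * i
        tree = maximal_spanning_tree(results_from_weights(W))
        assert len(tree.edges) == 4
        assert tree.total_weight == pytest.approx(sum(0.2 + 0.1 * i for i in range(4)))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 7))
        W = np.abs(random_weighted_graph(p, seed + 100, density=0.8))
        W = W + 0.01 * (np.ones((p, p)) - np.eye(p))
        np.fill_diagonal(W, 0.0)
        tree = maximal_spanning_tree(results_from_weights(W))
        assert tree.total_weight == pytest.approx(all_spanning_trees_max_weight(W))

    def test_agrees_with_kruskal(self, fitted12):
        _, _, res = fitted12
        tree = maximal_spanning_tree(res)
        G = res.to_graph()
        kruskal = nx.maximum_spanning_tree(G, weight="abs_weight")
        k_total = sum(d["abs_weight"] for _, _, d in kruskal.edges(data=True))
        assert tree.total_weight == pytest.approx(k_total)

    def test_disconnected_graph_yields_forest(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.4
        W[3, 4] = W[4, 3] = 0.3
        tree = maximal_spanning_tree(results_from_weights(W))
        assert len(tree.edges) == 3  # (2-1) + (3-1), isolated node excluded

    def test_signed_weights_preserved_in_output(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = -0.5
        W[1, 2] = W[2, 1] = 0.4
        tree = maximal_spanning_tree(results_from_weights(W))
        weights = {(u, v): w for u, v, w in tree.edges}
        assert min(weights.values()) < 0 < max(weights.values())
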