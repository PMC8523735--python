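"""Auto-CM training dynamics, weight-to-distance mapping and the MST map."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from osteomap.autocm import (
    AutoCMWeights,
    AutoContractiveMap,
    adjacency_report,
    minimum_spanning_tree,
    semantic_input,
    weights_to_distance,
)


def _offdiag_argmax(w):
    m = w.copy()
    np.fill_diagonal(m, -np.inf)
    return np.unravel_index(np.argmax(m), m.shape)


def _symmetrized(res):
    w = res.weights.w
    return (w + w.T) / 2.0


# ------------------------------------------------------------ training contracts


def test_duplicate_columns_attain_maximal_weight():
    rng = np.random.default_rng(0)
    x = rng.random(500)
    X = np.column_stack([x, x, rng.random(500), rng.random(500)])
    res = AutoContractiveMap(X).fit()
    assert res.weights.converged
    i, j = _offdiag_argmax(_symmetrized(res))
    assert {i, j} == {0, 1}


def test_correlated_pair_outranks_independent_column():
    """An r = 0.9 pair binds tighter than an independent column, across datasets."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((2000, 2))
        a, b = z[:, 0], 0.9 * z[:, 0] + np.sqrt(1 - 0.81) * z[:, 1]
        c = rng.standard_normal(2000)
        X = norm.cdf(np.column_stack([a, b, c]))  # identical uniform marginals
        w = _symmetrized(AutoContractiveMap(X).fit())
        wins += w[0, 1] > max(w[0, 2], w[1, 2])
    assert wins >= 9


def test_zero_column_gets_no_connection_growth():
    rng = np.random.default_rng(1)
    X = np.column_stack([rng.random(300), rng.random(300), np.zeros(300)])
    model = AutoContractiveMap(X)
    res = model.fit()
    init = AutoContractiveMap.INIT_FRACTION * model.C
    np.testing.assert_allclose(res.weights.w[2, :], init, atol=1e-12)


def test_weights_bounded_by_contraction_parameter():
    rng = np.random.default_rng(2)
    X = rng.random((400, 6))
    res = AutoContractiveMap(X).fit()
    assert np.all(res.weights.w < res.weights.C)
    assert np.all(res.weights.v < res.weights.C)
    assert np.all(res.weights.w >= 0) and np.all(res.weights.v >= 0)


def test_record_order_invariance():
    """Batch updates make training invariant to record permutation."""
    rng = np.random.default_rng(3)
    X = rng.random((200, 5))
    w1 = AutoContractiveMap(X).fit().weights.w
    w2 = AutoContractiveMap(X[rng.permutation(200)]).fit().weights.w
    np.testing.assert_allclose(w1, w2, atol=1e-10)


def test_inputs_outside_unit_interval_rejected():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        AutoContractiveMap(np.array([[0.5, 1.2], [0.1, 0.3]]))


# ------------------------------------------------------------ distances


def _weights_from_matrix(w):
    n = len(w)
    return AutoCMWeights(v=np.ones(n), w=np.asarray(w, float), C=float(n),
                         epochs=1, converged=True, final_output_activation=0.0,
                         columns=[f"x{j}" for j in range(n)])


def test_distance_definition_and_symmetry():
    w = np.array([[0.0, 4.0, 1.0], [4.0, 0.0, 2.0], [1.0, 2.0, 0.0]])
    d = weights_to_distance(_weights_from_matrix(w))
    assert d[0, 1] == 0.0  # maximal-weight pair at distance zero
    np.testing.assert_allclose(d, d.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(d), 0.0)
    assert d.min() >= 0 and d.max() <= 1


def test_distance_preserves_weight_ordering():
    rng = np.random.default_rng(4)
    w = rng.random((6, 6))
    w = (w + w.T) / 2
    d = weights_to_distance(_weights_from_matrix(w))
    iu = np.triu_indices(6, 1)
    order_w = np.argsort(w[iu])
    order_d = np.argsort(-d[iu])
    np.testing.assert_array_equal(order_w, order_d)


def test_untrained_weights_rejected():
    with pytest.raises(ValueError, match="untrained"):
        weights_to_distance(_weights_from_matrix(np.zeros((3, 3))))


# ------------------------------------------------------------ minimum spanning tree


def _prufer_tree_weight(seq, d):
    """Decode a Prüfer sequence and sum the edge distances of its tree."""
    n = len(seq) + 2
    degree = np.ones(n, int)
    for v in seq:
        degree[v] += 1
    total = 0.0
    seq = list(seq)
    for v in seq:
        leaf = min(i for i in range(n) if degree[i] == 1)
        total += d[leaf, v]
        degree[leaf] -= 1
        degree[v] -= 1
    u, v = [i for i in range(n) if degree[i] == 1]
    return total + d[u, v]


@pytest.mark.parametrize("n_instances", [20])
def test_mst_matches_exhaustive_spanning_tree_enumeration(n_instances):
    """Tree weight equals the minimum over all 125 labelled spanning trees."""
    rng = np.random.default_rng(5)
    for _ in range(n_instances):
        d = rng.random((5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = minimum_spanning_tree(d)
        brute = min(
            _prufer_tree_weight(seq, d)
            for seq in itertools.product(range(5), repeat=3)
        )
        assert tree.total_distance() == pytest.approx(brute, abs=1e-12)


def test_mst_is_a_spanning_tree():
    rng = np.random.default_rng(6)
    d = rng.random((9, 9))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    tree = minimum_spanning_tree(d)
    assert tree.graph.number_of_edges() == 8
    import networkx as nx

    assert nx.is_connected(tree.graph)


def test_mst_invariant_under_monotone_distance_transform():
    rng = np.random.default_rng(7)
    d = rng.random((7, 7))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    e1 = {tuple(sorted(e)) for e in minimum_spanning_tree(d).graph.edges()}
    e2 = {tuple(sorted(e)) for e in minimum_spanning_tree(d**2).graph.edges()}
    assert e1 == e2


def test_mst_rejects_asymmetric_input():
    d = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        minimum_spanning_tree(d)


def test_chain_correlated_variables_recover_chain_topology():
    """AR(1) columns with rho = 0.9 yield the chain as the semantic map."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n, k, rho = 2000, 5, 0.9
        z = np.empty((n, k))
        z[:, 0] = rng.standard_normal(n)
        for j in range(1, k):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        g = AutoContractiveMap(norm.cdf(z)).fit().mst()
        edges = {tuple(sorted(e)) for e in g.graph.edges()}
        chain = {tuple(sorted((f"x{j}", f"x{j+1}"))) for j in range(k - 1)}
        hits += edges == chain
    assert hits >= 9


# ------------------------------------------------------------ adjacency reports


@pytest.fixture(scope="module")
def toy_tree():
    d = np.array(
        [
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.2, 0.9],
            [0.9, 0.2, 0.0, 0.3],
            [0.8, 0.9, 0.3, 0.0],
        ]
    )
    return minimum_spanning_tree(d, columns=["a", "b", "c", "d"])


def test_leaf_node_has_one_neighbor(toy_tree):
    report = adjacency_report(toy_tree, "a")
    assert len(report) == 1 and report.loc[0, "neighbor"] == "b"


def test_adjacency_strengths_match_edge_dump(toy_tree):
    edges = toy_tree.edges()
    for node in toy_tree.nodes:
        for _, row in adjacency_report(toy_tree, node).iterrows():
            match = edges[
                ((edges.source == node) & (edges.target == row.neighbor))
                | ((edges.target == node) & (edges.source == row.neighbor))
            ]
            assert abs(float(match.strength.iloc[0]) - row.strength) < 1e-12


def test_unknown_node_rejected(toy_tree):
    with pytest.raises(KeyError, match="unknown node"):
        adjacency_report(toy_tree, "zzz")


def test_graph_exports(tmp_path, toy_tree):
    toy_tree.write_graphml(tmp_path / "map.graphml")
    toy_tree.write_edgelist_csv(tmp_path / "edges.csv")
    toy_tree.write_dot(tmp_path / "map.dot")
    import networkx as nx

    back = nx.read_graphml(tmp_path / "map.graphml")
    assert back.number_of_edges() == 3
    assert "semantic_map" in (tmp_path / "map.dot").read_text()


def test_semantic_input_appends_outcome_indicators():
    import pandas as pd

    df = pd.DataFrame({"a_high": [0.2, 0.8], "a_low": [0.8, 0.2]})
    out = semantic_input(df, [1, 0])
    assert list(out["new_fracture_yes"]) == [1.0, 0.0]
    assert list(out["new_fracture_no"]) == [0.0, 1.0]
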