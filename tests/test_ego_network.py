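"""Unit and property tests for per-ego graph construction and measures."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from egobp import ego_network as en
from conftest import graph_from_edges, ratings_from_edges
from oracles import brute_force_centralities, random_graph


# --- graph construction -----------------------------------------------------

def test_rating_threshold_defines_ties():
    """Pairs rated 4 or 5 are tied; 3 and below are not."""
    ratings = ratings_from_edges([], no_tie_rating=3)
    ratings.loc[(ratings.alter_i == 0) & (ratings.alter_j == 1), "rating"] = 4
    ratings.loc[(ratings.alter_i == 0) & (ratings.alter_j == 2), "rating"] = 3
    ratings.loc[(ratings.alter_i == 0) & (ratings.alter_j == 3), "rating"] = 5
    g = en.build_graph(ratings, [False] * 30)
    assert (0, 1) in g.edges and (0, 3) in g.edges
    assert (0, 2) not in g.edges
    assert g.n_edges == 2


@pytest.mark.parametrize("rating,n_edges", [(5, 435), (4, 435), (3, 0), (1, 0)])
def test_uniform_ratings_give_complete_or_empty_graph(rating, n_edges):
    ratings = ratings_from_edges([], no_tie_rating=rating)
    g = en.build_graph(ratings, [False] * 30)
    assert g.n_edges == n_edges


def _corrupt(ratings, how):
    r = ratings.copy()
    if how == "missing_pair":
        return r.iloc[:-1]
    if how == "duplicate_pair":
        return pd.concat([r, r.iloc[[0]]], ignore_index=True)
    if how == "rating_out_of_range":
        r.loc[0, "rating"] = 6
        return r
    if how == "self_pair":
        r.loc[0, ["alter_i", "alter_j"]] = (3, 3)
        return r
    if how == "index_out_of_range":
        r.loc[0, "alter_j"] = 30
        return r
    raise AssertionError(how)


@pytest.mark.parametrize("how", ["missing_pair", "duplicate_pair",
                                 "rating_out_of_range", "self_pair",
                                 "index_out_of_range"])
def test_build_graph_rejects_malformed_tables(how):
    ratings = ratings_from_edges([(0, 1)])
    with pytest.raises(en.NetworkValidationError):
        en.build_graph(_corrupt(ratings, how), [False] * 30, ego_id="E1")


# --- centralities on hand-checked graphs ------------------------------------

def test_path_graph_centralities():
    """0-1-2 path among 30 nodes: only the middle node carries paths."""
    g = graph_from_edges([(0, 1), (1, 2)])
    c = en.node_centralities(g)
    assert c.betweenness[1] == pytest.approx(1.0)
    assert c.betweenness[0] == 0 and c.betweenness[2] == 0
    assert c.betweenness[3:].sum() == 0
    mb, md = en.ego_structural_measures(g, c)
    assert md == pytest.approx(4 / 3)          # (1 + 1 + 2) / 3
    assert mb == pytest.approx(1 / 30)
    assert en.central_positions(g, c) == (1, 1, 0)  # farness tie 0 vs 2 -> 0


def test_star_graph_centralities():
    """Star, center 0, leaves 1-4: center brokers all C(4,2) leaf pairs."""
    g = graph_from_edges([(0, i) for i in range(1, 5)], n_alters=5,
                         family=[False, True, False, False, False])
    c = en.node_centralities(g)
    assert c.betweenness[0] == pytest.approx(6.0)
    assert np.all(c.betweenness[1:] == 0)
    assert c.farness[0] == pytest.approx(1.0)
    assert c.farness[1] == pytest.approx((1 + 2 * 3) / 4)
    pos = en.central_positions(g, c)
    assert pos == (0, 0, 1)                    # most distant: leaf, lowest index
    pct_family, pct_central = en.compositional_measures(g, pos)
    assert pct_family == pytest.approx(1 / 5)
    assert pct_central == pytest.approx(1 / 3)


def test_complete_graph_measures():
    g = graph_from_edges([(i, j) for i in range(30) for j in range(i + 1, 30)])
    c = en.node_centralities(g)
    assert np.allclose(c.betweenness, 0.0)
    assert np.allclose(c.harmonic_closeness, 29.0)
    mb, md = en.ego_structural_measures(g, c)
    assert md == 1.0 and mb == 0.0
    assert en.central_positions(g, c) == (0, 0, 0)  # all tied -> lowest index


def test_edgeless_graph_yields_missing_distance_and_warning():
    g = graph_from_edges([])
    c = en.node_centralities(g)
    with pytest.warns(UserWarning):
        mb, md = en.ego_structural_measures(g, c)
    assert mb == 0.0 and np.isnan(md)
    assert en.central_positions(g, c) == (-1, -1, -1)
    with pytest.warns(UserWarning):
        pf, pcf = en.compositional_measures(g, (-1, -1, -1))
    assert pcf == 0.0


def test_penalized_distance_convention_counts_unreachable_as_n():
    g = graph_from_edges([(0, 1)], n_alters=4)
    c = en.node_centralities(g)
    _, d_reach = en.ego_structural_measures(g, c, "reachable")
    _, d_pen = en.ego_structural_measures(g, c, "penalized")
    assert d_reach == 1.0
    assert d_pen == pytest.approx((1.0 + 5 * 4.0) / 6)


# --- oracle equivalence and invariants --------------------------------------

def test_centralities_match_networkx_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(40):
        n = int(rng.integers(4, 12))
        adj = random_graph(rng, n, float(rng.uniform(0.1, 0.9)))
        g = graph_from_edges(
            [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]],
            n_alters=n)
        c = en.node_centralities(g)
        G = nx.from_numpy_array(adj.astype(int))
        G.add_nodes_from(range(n))
        nx_b = nx.betweenness_centrality(G, normalized=False)
        assert np.allclose(c.betweenness, [nx_b[v] for v in range(n)], atol=1e-9)
        nx_h = nx.harmonic_centrality(G)
        assert np.allclose(c.harmonic_closeness, [nx_h[v] for v in range(n)],
                           atol=1e-9)


def test_brute_force_oracle_agreement_small_graphs():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = int(rng.integers(3, 9))
        adj = random_graph(rng, n, float(rng.uniform(0.1, 0.95)))
        g = graph_from_edges(
            [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]],
            n_alters=n)
        c = en.node_centralities(g)
        b, dist, harm, far = brute_force_centralities(adj)
        assert np.allclose(c.betweenness, b, atol=1e-9)
        assert np.array_equal(np.isfinite(c.distances), np.isfinite(dist))
        assert np.allclose(c.distances[np.isfinite(dist)],
                           dist[np.isfinite(dist)], atol=1e-9)
        assert np.allclose(c.harmonic_closeness, harm, atol=1e-9)


def test_betweenness_distance_identity_random_graphs():
    """Sum of betweenness equals sum over reachable pairs of (d - 1)."""
    rng = np.random.default_rng(3)
    for _ in range(60):
        adj = random_graph(rng, 30, float(rng.uniform(0.02, 0.6)))
        g = graph_from_edges(
            [(i, j) for i in range(30) for j in range(i + 1, 30) if adj[i, j]])
        c = en.node_centralities(g)
        iu = np.triu_indices(30, k=1)
        pair_d = c.distances[iu]
        finite = np.isfinite(pair_d)
        assert c.betweenness.sum() == pytest.approx(
            (pair_d[finite] - 1).sum(), abs=1e-8)


def test_adding_edge_never_increases_distance_on_connected_graphs():
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = 12
        # random connected graph: random tree plus extra edges
        edges = {(int(min(v, u)), int(max(v, u)))
                 for v in range(1, n) for u in [int(rng.integers(0, v))]}
        iu, ju = np.triu_indices(n, k=1)
        extra = rng.random(len(iu)) < 0.2
        edges |= {(int(i), int(j)) for i, j in zip(iu[extra], ju[extra])}
        missing = [(int(i), int(j)) for i, j in zip(iu, ju)
                   if (i, j) not in edges]
        if not missing:
            continue
        g = graph_from_edges(edges, n_alters=n)
        _, d0 = en.ego_structural_measures(g, en.node_centralities(g))
        new_edge = missing[int(rng.integers(len(missing)))]
        g2 = graph_from_edges(edges | {new_edge}, n_alters=n)
        _, d1 = en.ego_structural_measures(g2, en.node_centralities(g2))
        assert d1 <= d0 + 1e-12
        assert d1 >= 1.0


# --- study-level table -------------------------------------------------------

def _toy_study_tables():
    """Two egos: a 0-1-2 path with node 1 family, and a complete triangle
    0-1-2 (plus isolates) with no family."""
    ties_a = ratings_from_edges([(0, 1), (1, 2)])
    ties_a.insert(0, "participant_id", "A")
    ties_b = ratings_from_edges([(0, 1), (0, 2), (1, 2)])
    ties_b.insert(0, "participant_id", "B")
    ties = pd.concat([ties_a, ties_b], ignore_index=True)
    rel_a = ["1" if i == 1 else "4" for i in range(30)]
    rel_b = ["5;8"] * 30
    alters = pd.DataFrame({
        "participant_id": ["A"] * 30 + ["B"] * 30,
        "alter_index": list(range(30)) * 2,
        "relationship_codes": rel_a + rel_b,
        "alter_age": 40, "alter_sex": 1, "skin_tone": 3,
    })
    return ties, alters


def test_measures_table_matches_hand_computation():
    ties, alters = _toy_study_tables()
    tbl = en.compute_measures_table(ties, alters).set_index("participant_id")
    a = tbl.loc["A"]
    assert a.mean_betweenness == pytest.approx(1 / 30)
    assert a.mean_distance == pytest.approx(4 / 3)
    assert a.pct_family == pytest.approx(1 / 30)
    assert a.pct_central_family == pytest.approx(2 / 3)  # node 1 most between+close
    b = tbl.loc["B"]
    assert b.mean_betweenness == 0.0
    assert b.mean_distance == 1.0
    assert b.pct_family == 0.0 and b.pct_central_family == 0.0


def test_measures_table_is_order_independent_and_deterministic():
    ties, alters = _toy_study_tables()
    t1 = en.compute_measures_table(ties, alters)
    shuffled = ties.sample(frac=1, random_state=0)
    t2 = en.compute_measures_table(shuffled, alters)
    m1 = t1.set_index("participant_id").sort_index()
    m2 = t2.set_index("participant_id").sort_index()
    pd.testing.assert_frame_equal(m1, m2)


def test_family_flags_follow_relationship_codes():
    alters = pd.DataFrame({
        "participant_id": ["X"] * 4,
        "alter_index": [0, 1, 2, 3],
        "relationship_codes": ["1", "3", "4;2", "10"],
    })
    flags = en.family_flags_from_alters(alters)["X"]
    assert list(flags) == [True, True, True, False]
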