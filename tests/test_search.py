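"""Seed selection, greedy expansion and overlap merging."""

import itertools

import networkx as nx
import numpy as np
import pytest

from crossmod.data import Module
from crossmod.network import OrthogroupNetwork
from crossmod.scoring import BackgroundStats
from crossmod.search import (
    SearchConfig,
    expand_seed,
    merge_kept_edges,
    merge_modules,
    run_search,
    select_seeds,
)

from conftest import connected_subsets, network_from, oracle_module_score


# ------------------------------------------------------------------- seeds
def test_seed_ranking_and_tie_break():
    g = nx.empty_graph(["A", "B", "C"])
    net = network_from(g, {"A": 3.0, "B": 1.0, "C": 2.0})
    assert select_seeds(net, SearchConfig(n_seeds=2)) == ["A", "C"]

    tie = network_from(nx.empty_graph(["B", "A"]), {"A": 2.0, "B": 2.0})
    assert select_seeds(tie, SearchConfig(n_seeds=1)) == ["A"]

    assert select_seeds(net, SearchConfig(seed_threshold=10.0)) == []


# --------------------------------------------------------------- expansion
def test_star_expansion_matches_exhaustive_best_connected_subgraph(star_network):
    bg = BackgroundStats.from_network(star_network, beta=0.0, edge_weight=0.0)
    config = SearchConfig()
    mod = expand_seed("l0", star_network, bg, config)

    best_nodes, best_score = None, -np.inf
    for subset in connected_subsets(star_network.graph):
        s = oracle_module_score(subset, star_network, bg)
        if s > best_score:
            best_nodes, best_score = subset, s
    assert set(mod.nodes) == set(best_nodes)  # the full star
    assert mod.score == pytest.approx(best_score)


def test_expansion_stops_on_negative_neighbors_beyond_growth_floor():
    # hub of 5 good nodes (clique) with poor satellites
    g = nx.complete_graph([f"g{i}" for i in range(5)])
    for i in range(5):
        g.add_edge(f"g{i}", f"bad{i}")
    nx.set_edge_attributes(g, 1.0, "weight")
    scores = {f"g{i}": 4.0 for i in range(5)}
    scores.update({f"bad{i}": 0.0 for i in range(5)})
    net = network_from(g, scores)
    bg = BackgroundStats.from_network(net, beta=0.0, edge_weight=0.0)
    mod = expand_seed("g0", net, bg, SearchConfig(min_growth_size=5))
    assert set(mod.nodes) == {f"g{i}" for i in range(5)}


def test_equal_improvement_prefers_lexicographically_smaller_neighbor():
    g = nx.Graph([("s", "a"), ("s", "b")])
    nx.set_edge_attributes(g, 1.0, "weight")
    net = network_from(g, {"s": 3.0, "a": 2.0, "b": 2.0})
    bg = BackgroundStats.from_network(net, beta=0.0, edge_weight=0.0)
    mod = expand_seed("s", net, bg, SearchConfig())
    assert mod.trace[1][0] == ("s", "a")


def test_isolated_seed_returns_singleton():
    g = nx.empty_graph(["x", "y"])
    net = network_from(g, {"x": 5.0, "y": 1.0})
    bg = BackgroundStats.from_network(net, edge_weight=0.0)
    mod = expand_seed("x", net, bg, SearchConfig())
    assert mod.nodes == ("x",)


def test_returned_module_is_best_prefix_of_trace(star_network):
    bg = BackgroundStats.from_network(star_network, beta=0.0, edge_weight=0.0)
    mod = expand_seed("l0", star_network, bg, SearchConfig())
    scores = [s for _, s in mod.trace]
    assert mod.score == max(scores)
    assert mod.nodes == tuple(sorted(mod.trace[int(np.argmax(scores))][0]))


# ----------------------------------------------------------------- merging
def _merge_fixture():
    """Edge (a, b) co-contained in 2 modules; a appears in 4, b in 3."""
    g = nx.Graph([("a", "b")])
    g.add_nodes_from(["x", "y", "p", "q", "r"])
    nx.set_edge_attributes(g, 1.0, "weight")
    net = network_from(g, {n: 1.0 for n in g.nodes})
    modules = [
        Module(id="m1", nodes=("a", "b", "x")),
        Module(id="m2", nodes=("a", "b", "y")),
        Module(id="m3", nodes=("a", "p")),
        Module(id="m4", nodes=("a", "q")),
        Module(id="m5", nodes=("b", "r")),
    ]
    return net, modules


def test_merge_ratio_boundary_is_strict():
    net, modules = _merge_fixture()
    # ratio = 2 / max(4, 3) = 0.5
    assert merge_kept_edges(modules, net, cutoff=0.4) == {("a", "b")}
    assert merge_kept_edges(modules, net, cutoff=0.5) == set()


def test_edge_in_every_containing_module_always_kept():
    g = nx.Graph([("a", "b")])
    nx.set_edge_attributes(g, 1.0, "weight")
    net = network_from(g, {"a": 1.0, "b": 1.0})
    modules = [Module(id=f"m{i}", nodes=("a", "b")) for i in range(3)]
    assert merge_kept_edges(modules, net, cutoff=0.99) == {("a", "b")}


def test_disjoint_seed_modules_pass_through_unchanged():
    g = nx.Graph()
    g.add_edges_from(itertools.combinations(["a", "b", "c", "d"], 2))
    g.add_edges_from(itertools.combinations(["w", "x", "y", "z"], 2))
    nx.set_edge_attributes(g, 1.0, "weight")
    net = network_from(g, {n: 1.0 for n in g.nodes})
    modules = [Module(id="m1", nodes=("a", "b", "c", "d")),
               Module(id="m2", nodes=("w", "x", "y", "z"))]
    finals = merge_modules(modules, net, SearchConfig(merge_cutoff=0.25))
    assert sorted(m.node_set() for m in finals) == sorted(
        m.node_set() for m in modules
    )


def test_small_components_dropped_by_final_size_filter():
    net, modules = _merge_fixture()
    finals = merge_modules(
        modules, net, SearchConfig(merge_cutoff=0.4, min_final_module_size=4)
    )
    assert finals == []  # surviving component {a, b} is below the floor


def test_raising_cutoff_never_keeps_more_edges():
    import crossmod as cm

    net, truth = cm.generate_fixture(rng_seed=2)
    bg = BackgroundStats.from_network(net, rng_seed=2)
    config = SearchConfig()
    expansions = [
        expand_seed(s, net, bg, config) for s in select_seeds(net, config)
    ]
    counts = [
        len(merge_kept_edges(expansions, net, cutoff))
        for cutoff in (0.1, 0.2, 0.3, 0.4)
    ]
    assert counts == sorted(counts, reverse=True)


# --------------------------------------------------------------- full runs
def test_search_is_deterministic_and_modules_connected():
    import crossmod as cm

    net, _ = cm.generate_fixture(rng_seed=4)
    bg = BackgroundStats.from_network(net, rng_seed=4)
    mods_a = run_search(net, bg)
    mods_b = run_search(net, bg)
    assert [(m.id, m.nodes, m.score) for m in mods_a] == [
        (m.id, m.nodes, m.score) for m in mods_b
    ]
    for m in mods_a:
        assert m.size >= SearchConfig().min_final_module_size
        assert net.is_connected_subset(m.nodes)
    scores = [m.score for m in mods_a]
    assert scores == sorted(scores, reverse=True)


def test_uniform_zero_scores_yield_no_modules():
    g = nx.gnp_random_graph(30, 0.2, seed=1)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    net = network_from(g, {n: 0.0 for n in g.nodes})
    bg = BackgroundStats(mu_z=0.0, sigma_z=1.0, edge_weight=0.0)
    assert run_search(net, bg, SearchConfig(seed_threshold=0.0)) == []
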