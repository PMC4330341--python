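"""Shared fixtures and independent oracles for the test suite.

The oracle functions reimplement the objective, the hypergeometric tail
and exhaustive subgraph search from first principles, on purpose sharing
no code with the package, so agreement between the two paths is evidence
of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import networkx as nx
import numpy as np
import pytest

from crossmod.network import OrthogroupNetwork


# ------------------------------------------------------------------ oracles
def oracle_module_score(nodes, network, bg) -> float:
    """Direct, from-scratch evaluation of the module objective."""
    nodes = list(nodes)
    m = len(nodes)
    z_sum = sum(network.graph.nodes[n]["z"] for n in nodes)
    score = (z_sum - m * bg.beta * bg.mu_z) / (bg.sigma_z * math.sqrt(m))
    if bg.edge_weight != 0 and m > 1:
        e_sum = 0.0
        for u, v in itertools.combinations(nodes, 2):
            if network.graph.has_edge(u, v):
                e_sum += network.graph.edges[u, v]["weight"]
        mu_e, sigma_e = bg.edge_bg[m]
        if sigma_e == 0:
            edge_term = 0.0 if e_sum == mu_e else math.copysign(1e6, e_sum - mu_e)
        else:
            edge_term = (e_sum - mu_e) / sigma_e
        score += bg.edge_weight * edge_term
    return score


def connected_subsets(graph: nx.Graph, max_size: int | None = None):
    """All connected node subsets of a small graph (exhaustive)."""
    nodes = sorted(graph.nodes)
    max_size = max_size or len(nodes)
    for r in range(1, max_size + 1):
        for combo in itertools.combinations(nodes, r):
            if nx.is_connected(graph.subgraph(combo)):
                yield combo


def oracle_hypergeom_tail(universe: int, n_successes: int, n_draws: int, k: int) -> float:
    """P(X >= k) by exhaustive counting over all draw subsets."""
    total = comb(universe, n_draws)
    hits = 0
    for overlap in range(k, min(n_successes, n_draws) + 1):
        hits += comb(n_successes, overlap) * comb(
            universe - n_successes, n_draws - overlap
        )
    return hits / total


# ----------------------------------------------------------------- fixtures
def network_from(graph: nx.Graph, scores_a: dict, scores_b: dict | None = None,
                 species=("mouse", "macaque")) -> OrthogroupNetwork:
    """Wrap a weighted nx graph plus per-species scores into a network."""
    if scores_b is None:
        scores_b = dict(scores_a)
    edges = [
        (u, v, d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)
    ]
    return OrthogroupNetwork.from_scores(
        edges, {species[0]: scores_a, species[1]: scores_b}, species
    )


@pytest.fixture
def k4_network() -> OrthogroupNetwork:
    """Complete graph on 4 nodes, unit weights, distinct scores."""
    g = nx.complete_graph(["a", "b", "c", "d"])
    nx.set_edge_attributes(g, 1.0, "weight")
    scores = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
    return network_from(g, scores)


@pytest.fixture
def path5_network() -> OrthogroupNetwork:
    """Path a-b-c-d-e with unit weights."""
    g = nx.path_graph(["a", "b", "c", "d", "e"])
    nx.set_edge_attributes(g, 1.0, "weight")
    scores = {n: float(i) for i, n in enumerate("abcde", start=1)}
    return network_from(g, scores)


@pytest.fixture
def star_network() -> OrthogroupNetwork:
    """Star: center with score 0, six leaves with score 3."""
    leaves = [f"l{i}" for i in range(6)]
    g = nx.star_graph(["hub"] + leaves)
    nx.set_edge_attributes(g, 1.0, "weight")
    scores = {"hub": 0.0, **{l: 3.0 for l in leaves}}
    return network_from(g, scores)


def oracle_graph_suite() -> list[nx.Graph]:
    """Small connected graphs (<= 8 nodes) with varied weights and scores."""
    rng = np.random.default_rng(20240917)
    graphs = []
    for build in (
        lambda: nx.path_graph(5),
        lambda: nx.complete_graph(4),
        lambda: nx.cycle_graph(6),
        lambda: nx.star_graph(6),
        lambda: nx.connected_watts_strogatz_graph(8, 4, 0.3, seed=7),
        lambda: nx.barbell_graph(3, 1),
    ):
        g = nx.convert_node_labels_to_integers(build())
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.integers(1, 5))
        for n in g.nodes:
            g.nodes[n]["score_a"] = float(rng.normal(0, 2))
            g.nodes[n]["score_b"] = float(rng.normal(0, 2))
        graphs.append(g)
    return graphs


def suite_network(g: nx.Graph) -> OrthogroupNetwork:
    return network_from(
        g,
        {n: g.nodes[n]["score_a"] for n in g.nodes},
        {n: g.nodes[n]["score_b"] for n in g.nodes},
    )
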