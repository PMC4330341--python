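"""Null-model contracts and the planted-module fixture generator."""

import itertools

import networkx as nx
import numpy as np
import pytest

import crossmod as cm
from crossmod.synthetic import (
    PlantedModuleSpec,
    generate_fixture,
    generate_temporal_fixture,
    shuffle_expression,
    switch_edges,
    write_fixture,
)


@pytest.fixture
def planted_net():
    net, truth = generate_fixture(60, (PlantedModuleSpec(6, "opposite", 3.0),),
                                  rng_seed=8)
    return net, truth


# ------------------------------------------------------------ shuffle null
def test_shuffle_preserves_topology_and_score_multisets(planted_net):
    net, _ = planted_net
    null = shuffle_expression(net, rng_seed=3)
    assert set(null.graph.edges) == set(net.graph.edges)
    for u, v in net.graph.edges:
        assert null.edge_weight(u, v) == net.edge_weight(u, v)
    for sp in net.species:
        before = sorted(net.species_score(n, sp) for n in net.nodes)
        after = sorted(null.species_score(n, sp) for n in null.nodes)
        assert before == after
    # combined scores recomputed from the permuted per-species values
    for n in null.nodes:
        scores = null.graph.nodes[n]["scores"].values()
        assert null.combined_score(n) == max(abs(v) for v in scores)


def test_shuffle_is_seed_reproducible(planted_net):
    net, _ = planted_net
    a = shuffle_expression(net, rng_seed=5)
    b = shuffle_expression(net, rng_seed=5)
    c = shuffle_expression(net, rng_seed=6)
    score = lambda nw: [nw.graph.nodes[n]["scores"] for n in nw.nodes]
    assert score(a) == score(b)
    assert score(a) != score(c)


# ------------------------------------------------------------- switch null
def test_switch_preserves_degree_sequence_and_edge_count(planted_net):
    net, _ = planted_net
    null = switch_edges(net, rng_seed=4)
    assert dict(null.graph.degree()) == dict(net.graph.degree())
    assert null.graph.number_of_edges() == net.graph.number_of_edges()
    assert set(null.graph.edges) != set(net.graph.edges)  # actually rewired
    # weight multiset travels with the edges
    w = lambda nw: sorted(d["weight"] for _, _, d in nw.graph.edges(data=True))
    assert w(null) == w(net)


def test_switch_on_four_cycle_stays_two_regular():
    # every admissible swap on a 4-cycle would create a multi-edge, so the
    # cycle is the unique simple 2-regular outcome
    g = nx.cycle_graph(["a", "b", "c", "d"])
    nx.set_edge_attributes(g, 1.0, "weight")
    from conftest import network_from

    net = network_from(g, {n: 1.0 for n in g.nodes})
    null = switch_edges(net, n_swaps=200, rng_seed=1)
    assert sorted(dict(null.graph.degree()).values()) == [2, 2, 2, 2]
    assert set(map(frozenset, null.graph.edges)) == set(map(frozenset, g.edges))


def test_switch_too_few_edges_returns_input():
    g = nx.Graph([("a", "b")])
    nx.set_edge_attributes(g, 1.0, "weight")
    from conftest import network_from

    net = network_from(g, {"a": 1.0, "b": 1.0})
    null = switch_edges(net, rng_seed=0)
    assert set(null.graph.edges) == {("a", "b")}


# --------------------------------------------------------------- generator
def test_planted_blocks_are_connected_dense_and_patterned():
    specs = (
        PlantedModuleSpec(8, "conserved", 3.0),
        PlantedModuleSpec(8, "species_a", 3.0),
        PlantedModuleSpec(8, "opposite", 3.0),
    )
    net, truth = generate_fixture(200, specs, rng_seed=11)
    assert len(net) == 200
    sa, sb = net.species
    for block, pattern in zip(truth.modules, truth.patterns):
        assert net.is_connected_subset(block)
        za = np.array([net.species_score(n, sa) for n in block])
        zb = np.array([net.species_score(n, sb) for n in block])
        if pattern == "conserved":
            assert np.all(np.sign(za) == np.sign(zb))
            assert np.all(np.abs(za) > 1.0) and np.all(np.abs(zb) > 1.0)
        elif pattern == "opposite":
            assert np.all(np.sign(za) == -np.sign(zb))
        elif pattern == "species_a":
            assert np.all(np.abs(za) > 1.0)
    # planted blocks do not touch each other directly
    for b1, b2 in itertools.combinations(truth.modules, 2):
        assert not any(net.graph.has_edge(u, v) for u in b1 for v in b2)


def test_infeasible_plant_raises():
    with pytest.raises(ValueError, match="plant"):
        generate_fixture(10, (PlantedModuleSpec(8), PlantedModuleSpec(8)))


def test_fixture_files_are_byte_identical_for_same_seed(tmp_path):
    net, truth = generate_fixture(40, (PlantedModuleSpec(5, "conserved", 3.0),),
                                  rng_seed=2)
    d1, d2 = tmp_path / "run1", tmp_path / "run2"
    p1 = write_fixture(net, truth, d1)
    p2 = write_fixture(net, truth, d2)
    assert p1.keys() == p2.keys()
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()


def test_fixture_files_rebuild_the_generated_network(tmp_path):
    """Scoring the emitted expression files and reassembling the joint
    network reproduces the generated node scores and edge weights."""
    import crossmod.io as cio
    from crossmod.network import build_joint_network
    from crossmod.scoring import score_genes

    net, truth = generate_fixture(40, (PlantedModuleSpec(5, "opposite", 3.0),),
                                  rng_seed=6)
    paths = write_fixture(net, truth, tmp_path)
    sa, sb = net.species
    orth = cio.read_orthology(paths["orthology"])
    scores = {}
    for sp in (sa, sb):
        treat = cio.read_expression_table(paths[f"expr_{sp}_treatment"], sp, "t")
        ctrl = cio.read_expression_table(paths[f"expr_{sp}_control"], sp, "c")
        scores[sp] = score_genes(treat, ctrl)
    inter = {sp: cio.read_interactions(paths[f"edges_{sp}"], sp) for sp in (sa, sb)}
    rebuilt = build_joint_network(inter, orth, scores)
    assert set(rebuilt.nodes) == set(net.nodes)
    for n in net.nodes:
        for sp in (sa, sb):
            assert rebuilt.species_score(n, sp) == pytest.approx(
                net.species_score(n, sp), abs=1e-6
            )
    for u, v, d in net.graph.edges(data=True):
        assert rebuilt.edge_weight(u, v) == pytest.approx(d["weight"])


def test_temporal_fixture_schedule_grows_and_networks_share_topology():
    nets, truth = generate_temporal_fixture(rng_seed=3)
    times = list(nets)
    base_edges = set(nets[times[0]].graph.edges)
    for t in times[1:]:
        assert set(nets[t].graph.edges) == base_edges
    sizes = [len(truth.schedule[t][0]) for t in times]
    assert sizes == sorted(sizes)
    assert sizes[-1] == len(truth.modules[0])
    transient = [len(truth.schedule[t][1]) for t in times]
    assert sum(1 for x in transient if x > 0) == 1


def test_real_fixture_beats_shuffled_null_on_module_quality():
    """Modules on planted data score higher and are more activated than
    modules on expression-shuffled counterparts (paired comparison)."""
    wins_top = wins_meanz = n = 0
    for seed in range(5):
        net, _ = generate_fixture(rng_seed=seed)
        bg = cm.BackgroundStats.from_network(net, rng_seed=seed)
        mods = cm.run_search(net, bg)
        null = shuffle_expression(net, rng_seed=seed + 1000)
        bgn = cm.BackgroundStats.from_network(null, rng_seed=seed)
        nmods = cm.run_search(null, bgn)
        top = lambda ms: max((m.score for m in ms), default=-np.inf)
        meanz = lambda ms, nw: (
            np.mean([nw.combined_score(x) for m in ms for x in set(m.nodes)])
            if ms
            else 0.0
        )
        wins_top += top(mods) > top(nmods)
        wins_meanz += meanz(mods, net) > meanz(nmods, null)
        n += 1
    assert wins_top == n
    assert wins_meanz == n
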