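"""Node scores, backgrounds and the module objective."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossmod.network import OrthogroupNetwork
from crossmod.scoring import (
    BackgroundStats,
    EdgeBackgroundUnavailable,
    calibrate_edge_background,
    fit_node_background,
    module_node_component,
    module_score,
    node_score,
)

from conftest import network_from


# ------------------------------------------------------------- node scores
def test_node_score_is_z_of_treatment_mean_under_control_gaussian():
    assert node_score([2.0, 2.0], [1.0, -1.0]) == pytest.approx(
        2.0 / np.std([1.0, -1.0], ddof=1)
    )
    assert node_score([0.5, 1.5], [1.0, 1.0, 1.0], control_sd=1.0) == 0.0
    assert node_score([3.0], [0.0], control_sd=2.0) == 1.5


def test_node_score_degenerate_control_sd():
    with pytest.raises(ValueError, match="control SD is zero"):
        node_score([1.0], [2.0, 2.0])
    assert node_score([1.0], [2.0, 2.0], sd_floor=0.5) == -2.0
    with pytest.raises(ValueError, match=">= 2 control samples"):
        node_score([1.0], [2.0])


# --------------------------------------------------------- node background
def test_node_background_two_point_and_degenerate():
    net = network_from(__import__("networkx").empty_graph(["a", "b"]),
                       {"a": 1.0, "b": 3.0})
    mu, sigma = fit_node_background(net)
    assert mu == 2.0
    assert sigma == pytest.approx(math.sqrt(2.0))

    flat = network_from(__import__("networkx").empty_graph(["a", "b"]),
                        {"a": 5.0, "b": 5.0})
    with pytest.raises(ValueError, match="identical"):
        fit_node_background(flat)


def test_node_background_recovers_generating_parameters():
    """1000 normal draws: fitted (mu, sigma) within 3 standard errors."""
    rng = np.random.default_rng(42)
    true_mu, true_sigma, n = 5.0, 1.0, 1000  # all draws positive w.h.p.
    scores = {f"n{i}": float(v) for i, v in enumerate(rng.normal(true_mu, true_sigma, n))}
    net = OrthogroupNetwork.from_scores([], {"mouse": scores, "macaque": scores},
                                        ("mouse", "macaque"))
    # combined score = |most extreme| of identical values = |value|; keep
    # values positive so the abs has no effect
    assert min(scores.values()) > 0
    mu, sigma = fit_node_background(net)
    assert abs(mu - true_mu) < 3 * true_sigma / math.sqrt(n)
    assert abs(sigma - true_sigma) < 3 * true_sigma / math.sqrt(2 * (n - 1))


# --------------------------------------------------------- edge background
def test_edge_background_known_values(k4_network, path5_network):
    bg = calibrate_edge_background(k4_network, [1, 3], n_samples=50, rng_seed=0)
    assert bg[1] == (0.0, 0.0)
    mu, sd = bg[3]  # every 3-subset of K4 induces exactly 3 unit edges
    assert mu == 3.0 and sd == 0.0

    bg = calibrate_edge_background(path5_network, [3], n_samples=50, rng_seed=0)
    mu, sd = bg[3]  # every connected 3-subset of a path has exactly 2 edges
    assert mu == 2.0 and sd == 0.0


def test_edge_background_reproducible_and_order_independent(k4_network):
    a = calibrate_edge_background(k4_network, [2, 3, 4], n_samples=200, rng_seed=9)
    b = calibrate_edge_background(k4_network, [4, 3, 2], n_samples=200, rng_seed=9)
    assert a == b


def test_edge_background_unavailable_size(path5_network):
    with pytest.raises(EdgeBackgroundUnavailable):
        calibrate_edge_background(path5_network, [6], n_samples=10, rng_seed=0)


# ---------------------------------------------------------- the objective
def _bg(mu, sigma, **kw):
    return BackgroundStats(mu_z=mu, sigma_z=sigma, **kw)


def test_node_component_formula_values():
    bg = _bg(0.5, 1.0, beta=1.0)
    assert module_node_component([2.0], bg) == pytest.approx(1.5)
    bg = _bg(1.0, 2.0, beta=1.0)
    assert module_node_component([2.0, 2.0, 2.0, 2.0], bg) == pytest.approx(1.0)
    # centred scores give 0 for any module size
    bg = _bg(3.0, 1.5, beta=0.8)
    centred = bg.beta * bg.mu_z
    for m in (1, 2, 7):
        assert module_node_component([centred] * m, bg) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        module_node_component([], bg)


def test_module_score_reduces_to_node_component_when_w_zero(k4_network):
    bg = BackgroundStats.from_network(k4_network, edge_weight=0.0)
    nodes = ["a", "b", "c"]
    z = [k4_network.combined_score(n) for n in nodes]
    assert module_score(nodes, k4_network, bg) == pytest.approx(
        module_node_component(z, bg)
    )


def test_module_score_size_one_has_no_edge_term(k4_network):
    bg = BackgroundStats.from_network(k4_network, edge_weight=5.0)
    z = k4_network.combined_score("d")
    expected = (z - bg.beta * bg.mu_z) / bg.sigma_z
    assert module_score(["d"], k4_network, bg) == pytest.approx(expected)


def test_module_score_edge_term_against_hand_computation(k4_network):
    # noisy-weight K4 variant so sigma_E(3) is non-degenerate
    noisy = k4_network.copy()
    weights = {("a", "b"): 1.0, ("a", "c"): 2.0, ("a", "d"): 1.0,
               ("b", "c"): 3.0, ("b", "d"): 1.0, ("c", "d"): 2.0}
    for (u, v), w in weights.items():
        noisy.graph.edges[u, v]["weight"] = w
    bg = BackgroundStats.from_network(
        noisy, edge_weight=1.0, n_bg_samples=400, rng_seed=3
    )
    mu_e, sigma_e = bg.edge_stats(3, noisy)
    assert sigma_e > 0
    nodes = ["a", "b", "c"]
    internal = weights[("a", "b")] + weights[("a", "c")] + weights[("b", "c")]
    z = [noisy.combined_score(n) for n in nodes]
    expected = module_node_component(z, bg) + 1.0 * (internal - mu_e) / sigma_e
    assert module_score(nodes, noisy, bg) == pytest.approx(expected)


def test_degenerate_sigma_e_caps_with_warning(k4_network):
    bg = BackgroundStats.from_network(k4_network, edge_weight=1.0)
    bg.edge_bg[2] = (0.5, 0.0)  # forced degenerate background
    with pytest.warns(RuntimeWarning, match="capping"):
        s = module_score(["a", "b"], k4_network, bg)
    assert s > 1e5


def test_missing_edge_background_errors_without_lazy_network(k4_network):
    bg = BackgroundStats(mu_z=1.0, sigma_z=1.0, edge_weight=1.0)
    with pytest.raises(EdgeBackgroundUnavailable, match="calibrate"):
        module_score(["a", "b", "c"], k4_network, bg, lazy_calibrate=False)


def test_background_stats_json_roundtrip(tmp_path, k4_network):
    bg = BackgroundStats.from_network(
        k4_network, beta=1.2, edge_weight=0.7, n_bg_samples=50,
        rng_seed=11, precalibrate_sizes=[1, 2, 3],
    )
    p = tmp_path / "bg.json"
    bg.save(p)
    again = BackgroundStats.load(p)
    assert again == bg


@settings(deadline=None, derandomize=True)
@given(
    scores=st.lists(st.floats(-5, 5), min_size=1, max_size=8),
    beta=st.floats(0, 2),
)
def test_node_component_invariant_under_reordering(scores, beta):
    bg = _bg(0.7, 1.3, beta=beta)
    fwd = module_node_component(scores, bg)
    rev = module_node_component(list(reversed(scores)), bg)
    assert fwd == pytest.approx(rev, abs=1e-9)


def test_node_only_objective_is_standard_normal_under_null():
    """beta=0, W=0, N(0,1) node scores: random-module scores ~ N(0,1)."""
    import networkx as nx
    from scipy.stats import kstest

    from crossmod.scoring import sample_connected_subset

    rng = np.random.default_rng(5)
    g = nx.gnp_random_graph(300, 0.03, seed=10)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    net = network_from(g, {n: 0.0 for n in g.nodes})
    bg = BackgroundStats(mu_z=0.0, sigma_z=1.0, beta=0.0, edge_weight=0.0)
    draws = []
    for _ in range(400):
        subset = sample_connected_subset(net, 8, rng)
        # fresh scores per module: the claim is unconditional on any one
        # realized score vector (which would shift the mean by mu_hat)
        for n in subset:
            net.graph.nodes[n]["z"] = float(rng.normal())
        draws.append(module_score(subset, net, bg))
    assert kstest(np.array(draws), "norm").pvalue > 0.01
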