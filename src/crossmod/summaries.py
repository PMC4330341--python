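"""Summary statistics of a module set and small reporting helpers."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import Module, OrthologyMap
from .network import OrthogroupNetwork

__all__ = [
    "percentage",
    "edges_to_nodes_ratio",
    "graph_density",
    "orthogroup_size_percentages",
    "de_node_fraction",
    "module_set_summary",
]


def percentage(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator (0 for an empty denominator)."""
    return 100.0 * numerator / denominator if denominator else 0.0


def edges_to_nodes_ratio(n_edges: int, n_nodes: int) -> float:
    if n_nodes <= 0:
        return 0.0
    return n_edges / n_nodes


def graph_density(n_edges: int, n_nodes: int) -> float:
    if n_nodes < 2:
        return 0.0
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


def orthogroup_size_percentages(member_counts: Mapping[str, int] | Sequence[int]) -> dict[int, float]:
    """Percent of orthogroups having each member count.

    Accepts either an orthogroup -> member-count mapping (as produced by
    :meth:`OrthologyMap.member_counts`) or a bare sequence of counts.
    """
    counts = (
        list(member_counts.values())
        if isinstance(member_counts, Mapping)
        else list(member_counts)
    )
    total = len(counts)
    out: dict[int, float] = {}
    for c in counts:
        out[c] = out.get(c, 0) + 1
    return {size: percentage(n, total) for size, n in sorted(out.items())}


def de_node_fraction(
    network: OrthogroupNetwork, nodes: Iterable[str], threshold: float = 0.25
) -> float:
    """Fraction of differentially expressed nodes among ``nodes``.

    A node counts as DE when its combined score, scaled by the network-wide
    maximum (so scores live on a [0, 1] scale), exceeds ``threshold``.
    """
    nodes = list(nodes)
    if not nodes:
        return 0.0
    zmax = float(network.score_array().max())
    if zmax == 0:
        return 0.0
    return float(np.mean([network.combined_score(n) / zmax > threshold for n in nodes]))


def module_set_summary(
    modules: Sequence[Module],
    network: OrthogroupNetwork,
    de_threshold: float = 0.25,
) -> dict:
    """Headline numbers of a final module set.

    Unique nodes and unique internal edges over all modules, the
    edges-to-nodes ratio, the density of the module-induced graph, and
    the DE-node percentage.
    """
    nodes = {n for m in modules for n in m.nodes}
    edges: set[tuple[str, str]] = set()
    for m in modules:
        members = m.node_set()
        for u in members:
            for v in network.graph[u]:
                if v in members and u < v:
                    edges.add((u, v))
    return {
        "n_modules": len(modules),
        "n_nodes": len(nodes),
        "n_edges": len(edges),
        "edges_to_nodes_ratio": edges_to_nodes_ratio(len(edges), len(nodes)),
        "density": graph_density(len(edges), len(nodes)),
        "pct_de_nodes": 100.0 * de_node_fraction(network, nodes, de_threshold),
    }
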