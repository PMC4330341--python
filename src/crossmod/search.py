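"""Seed selection, greedy seed expansion, and overlap-based module merging.

The search expands every seed node by breadth-first greedy growth: at each
step the frontier neighbour that maximises the module objective is added.
While the module is smaller than ``min_growth_size`` the best neighbour is
added even if the score does not improve (this lets a strong seed climb out
of a locally flat start); afterwards growth stops as soon as no single
addition strictly increases the score, and the best-scoring prefix of the
growth trajectory is returned.

Seed modules overlap heavily, so they are merged by an edge-frequency rule:
an edge e(a, b) that appears inside any seed module is kept iff

    #modules containing both a and b
    --------------------------------------------------  >  cutoff
    max(#modules containing a, #modules containing b)

and the final modules are the connected components of the kept-edge graph
(components below ``min_final_module_size`` are dropped).  Edges visited
from many different seeds are the ones most likely to be genuine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .data import Module, canonical_pair
from .network import OrthogroupNetwork
from .scoring import BackgroundStats, module_score

log = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "select_seeds",
    "expand_seed",
    "merge_kept_edges",
    "merge_modules",
    "run_search",
]


@dataclass
class SearchConfig:
    """Tunable knobs of the module search.

    Seeds: explicit top-``n_seeds``, or every node with combined score
    above ``seed_threshold``; when neither is given, all nodes above the
    ``seed_percentile``-th percentile of combined scores are used.

    ``merge_cutoff`` is the strict lower bound on the edge co-appearance
    ratio (sensible range 0.1-0.4).  ``merge_count`` selects the numerator
    variant: ``"node"`` counts modules containing both endpoints; for
    modules that are induced subgraphs — as produced here — the edge-level
    variant coincides with it, so the switch exists for forward
    compatibility with searches that track traversed edges explicitly.
    """

    n_seeds: Optional[int] = None
    seed_threshold: Optional[float] = None
    seed_percentile: float = 95.0
    min_growth_size: int = 5
    min_final_module_size: int = 4
    merge_cutoff: float = 0.25
    merge_count: str = "node"
    max_module_size: int = 150

    def __post_init__(self) -> None:
        if not (0.0 < self.merge_cutoff < 1.0):
            raise ValueError("merge_cutoff must lie strictly between 0 and 1")
        if self.min_final_module_size < 1:
            raise ValueError("min_final_module_size must be >= 1")
        if self.merge_count not in ("node", "edge"):
            raise ValueError("merge_count must be 'node' or 'edge'")


def select_seeds(network: OrthogroupNetwork, config: SearchConfig) -> list[str]:
    """Seed nodes ranked by combined score (descending, ties lexicographic)."""
    ranked = sorted(network.nodes, key=lambda n: (-network.combined_score(n), n))
    if config.n_seeds is not None:
        return ranked[: config.n_seeds]
    if config.seed_threshold is not None:
        threshold = config.seed_threshold
    else:
        threshold = float(
            np.percentile(network.score_array(ranked), config.seed_percentile)
        )
    seeds = [n for n in ranked if network.combined_score(n) > threshold]
    if not seeds:
        log.warning("no node passes the seed threshold %.4g", threshold)
    return seeds


def expand_seed(
    seed: str,
    network: OrthogroupNetwork,
    bg: BackgroundStats,
    config: SearchConfig,
) -> Module:
    """Greedy breadth-first expansion of one seed.

    Returns the best-scoring prefix of the growth trajectory as a
    :class:`Module`; its ``trace`` attribute holds the full trajectory as
    ``[(node_tuple, score), ...]`` for inspection and testing.  An
    isolated seed yields a single-node module (filtered later by size).
    """
    if seed not in network.graph:
        raise KeyError(f"seed {seed!r} not in network")
    members: list[str] = [seed]
    member_set = {seed}
    frontier = {nb for nb in network.graph[seed]}
    current = module_score(members, network, bg)
    trace: list[tuple[tuple[str, ...], float]] = [((seed,), current)]

    while frontier and len(members) < config.max_module_size:
        best_node: Optional[str] = None
        best_score = -np.inf
        for cand in sorted(frontier):  # lexicographic tie-break: first strict max
            s = module_score(members + [cand], network, bg)
            if s > best_score:
                best_score = s
                best_node = cand
        assert best_node is not None
        if len(members) >= config.min_growth_size and best_score <= current:
            break
        members.append(best_node)
        member_set.add(best_node)
        frontier.discard(best_node)
        for nb in network.graph[best_node]:
            if nb not in member_set:
                frontier.add(nb)
        current = best_score
        trace.append((tuple(members), current))

    best_idx = int(np.argmax([s for _, s in trace]))
    best_nodes, best = trace[best_idx]
    mod = Module(id=f"seed:{seed}", nodes=best_nodes, score=best, seed=seed)
    mod.trace = trace
    return mod


def merge_kept_edges(
    modules: Sequence[Module],
    network: OrthogroupNetwork,
    cutoff: float,
) -> set[tuple[str, str]]:
    """Edges surviving the co-appearance filter at the given cutoff.

    For every edge internal to at least one module, the number of modules
    containing both endpoints is divided by the larger of the endpoints'
    module-appearance counts; the edge is kept iff the ratio is strictly
    above ``cutoff``.  Because modules are induced subgraphs, counting
    modules in which the edge is internal gives the same numerator as
    counting co-membership of its endpoints.
    """
    node_count: dict[str, int] = {}
    pair_count: dict[tuple[str, str], int] = {}
    for mod in modules:
        nodes = mod.node_set()
        for n in nodes:
            node_count[n] = node_count.get(n, 0) + 1
        for u in nodes:
            for v in network.graph[u]:
                if v in nodes and u < v:
                    pair_count[(u, v)] = pair_count.get((u, v), 0) + 1
    return {
        (u, v)
        for (u, v), num in pair_count.items()
        if num / max(node_count[u], node_count[v]) > cutoff
    }


def merge_modules(
    modules: Sequence[Module],
    network: OrthogroupNetwork,
    config: SearchConfig,
    bg: Optional[BackgroundStats] = None,
) -> list[Module]:
    """Merge overlapping seed modules via the edge co-appearance ratio.

    Final modules are the connected components of the kept-edge graph,
    re-scored with the objective when ``bg`` is given, sorted by score
    (descending) and renamed ``M1, M2, ...``.
    """
    kept = nx.Graph()
    kept.add_edges_from(merge_kept_edges(modules, network, config.merge_cutoff))

    finals: list[Module] = []
    for comp in nx.connected_components(kept):
        if len(comp) < config.min_final_module_size:
            continue
        nodes = tuple(sorted(comp))
        score = None
        if bg is not None:
            score = module_score(nodes, network, bg)
        finals.append(Module(id="", nodes=nodes, score=score))
    if not finals:
        log.warning("no edge survived merging (cutoff %.3g)", config.merge_cutoff)
    finals.sort(key=lambda m: (-(m.score if m.score is not None else 0.0), m.nodes))
    for i, mod in enumerate(finals, start=1):
        mod.id = f"M{i}"
    return finals


def run_search(
    network: OrthogroupNetwork,
    bg: BackgroundStats,
    config: Optional[SearchConfig] = None,
    *,
    time_point: Optional[str] = None,
) -> list[Module]:
    """Full deterministic search: seeds -> expansions -> merge -> re-score."""
    config = config or SearchConfig()
    seeds = select_seeds(network, config)
    expansions = [expand_seed(s, network, bg, config) for s in seeds]
    finals = merge_modules(expansions, network, config, bg)
    if time_point is not None:
        for m in finals:
            m.time_point = time_point
    return finals
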