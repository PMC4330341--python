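"""Joint cross-species orthogroup network assembly.

Nodes are orthogroups.  Each node carries one signed activation score per
species (the most extreme signed z among that species' member genes, or the
paralog mean if requested) and a combined non-negative score: the absolute
value of the most extreme member score over all species, with the achieving
sign kept as metadata.  Edges connect two orthogroups whenever any member
gene of one interacts with any member gene of the other in any species; the
edge weight is the total evidence count over all such interactions, so an
interaction seen in several species accumulates support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .data import InteractionSet, OrthologyMap

log = logging.getLogger(__name__)

__all__ = ["OrthogroupNetwork", "build_joint_network"]


@dataclass
class OrthogroupNetwork:
    """A simple undirected graph over orthogroups with scores and weights.

    Node attributes on ``graph``:

    ``scores``  dict species -> signed per-species score (may omit species)
    ``z``       combined non-negative score (abs of most extreme member)
    ``sign``    +1/-1, the sign of the value achieving ``z``

    Edge attribute ``weight`` is the summed evidence count (>= 1).
    """

    graph: nx.Graph
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        self.species = tuple(self.species)

    # -- node accessors -------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def combined_score(self, node: str) -> float:
        return float(self.graph.nodes[node]["z"])

    def species_score(self, node: str, species: str) -> Optional[float]:
        val = self.graph.nodes[node]["scores"].get(species)
        return None if val is None else float(val)

    def combined_scores(self) -> dict[str, float]:
        return {n: float(d["z"]) for n, d in self.graph.nodes(data=True)}

    def score_array(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        order = self.nodes if order is None else list(order)
        return np.array([self.graph.nodes[n]["z"] for n in order], dtype=float)

    # -- edges ----------------------------------------------------------
    def edge_weight(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["weight"])

    def internal_edge_sum(self, nodes: Iterable[str]) -> float:
        """Summed weight of edges with both endpoints in ``nodes``."""
        members = set(nodes)
        total = 0.0
        for u in members:
            for v, attrs in self.graph[u].items():
                if v in members and u < v:
                    total += attrs["weight"]
        return total

    def is_connected_subset(self, nodes: Iterable[str]) -> bool:
        members = list(nodes)
        if not members:
            return False
        sub = self.graph.subgraph(members)
        return nx.is_connected(sub)

    def copy(self) -> "OrthogroupNetwork":
        # deep copy: nx's shallow copy would share the nested score dicts
        import copy as _copy

        return OrthogroupNetwork(_copy.deepcopy(self.graph), self.species)

    # -- construction helpers -------------------------------------------
    @staticmethod
    def from_scores(
        edges: Iterable[tuple[str, str, float]],
        species_scores: Mapping[str, Mapping[str, float]],
        species: Sequence[str],
    ) -> "OrthogroupNetwork":
        """Build directly from per-node per-species signed scores.

        Used by the synthetic generator and the expression shuffler; the
        combined score is recomputed from the per-species values.
        """
        g = nx.Graph()
        all_nodes: set[str] = set()
        for sp in species:
            all_nodes.update(species_scores.get(sp, {}))
        for node in sorted(all_nodes):
            scores = {
                sp: float(species_scores[sp][node])
                for sp in species
                if node in species_scores.get(sp, {})
            }
            z, sign = _combine(scores.values())
            g.add_node(node, scores=scores, z=z, sign=sign)
        for u, v, w in edges:
            if u == v:
                continue
            if g.has_edge(u, v):
                g.edges[u, v]["weight"] += float(w)
            else:
                g.add_edge(u, v, weight=float(w))
        return OrthogroupNetwork(g, tuple(species))


def _combine(values: Iterable[float]) -> tuple[float, int]:
    """Absolute of the most extreme signed value, plus its sign."""
    best = 0.0
    sign = 1
    found = False
    for v in values:
        if not found or abs(v) > abs(best) or (abs(v) == abs(best) and v > best):
            best = v
            sign = 1 if v >= 0 else -1
            found = True
    return (abs(best), sign) if found else (0.0, 1)


def _aggregate(values: list[float], how: str) -> float:
    if how == "extreme":
        # signed value of largest magnitude; on an exact +/- tie take the
        # positive one so the choice is deterministic
        return max(values, key=lambda v: (abs(v), v))
    if how == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown paralog aggregation {how!r}")


def build_joint_network(
    interactions: Mapping[str, InteractionSet],
    orthology: OrthologyMap,
    scores: Mapping[str, Mapping[str, float]],
    *,
    paralog_agg: str = "extreme",
    allow_self_loops: bool = False,
) -> OrthogroupNetwork:
    """Assemble the joint cross-species orthogroup network.

    Parameters
    ----------
    interactions:
        species label -> :class:`InteractionSet`.
    orthology:
        gene -> orthogroup map; genes absent from it are dropped (logged).
    scores:
        species label -> {gene: signed differential-expression z}.
    paralog_agg:
        ``"extreme"`` (default; signed value of largest magnitude among the
        species' member genes) or ``"mean"``.
    allow_self_loops:
        interactions inside a single orthogroup are dropped unless set; the
        module objective is defined over edges between distinct nodes, so
        the default builds a simple graph.

    Returns
    -------
    OrthogroupNetwork whose node set is every orthogroup with at least one
    scored member gene in at least one species.
    """
    species = tuple(scores)
    if not species:
        raise ValueError("no species provided")

    # per-orthogroup, per-species member score lists
    member_scores: dict[str, dict[str, list[float]]] = {}
    n_unmapped = 0
    for sp, gene_scores in scores.items():
        for gene, val in gene_scores.items():
            group = orthology.group_of(gene)
            if group is None:
                n_unmapped += 1
                continue
            member_scores.setdefault(group, {}).setdefault(sp, []).append(float(val))
    if n_unmapped:
        log.info("dropped %d scored genes absent from the orthology map", n_unmapped)

    g = nx.Graph()
    for group in sorted(member_scores):
        per_sp = {
            sp: _aggregate(vals, paralog_agg)
            for sp, vals in member_scores[group].items()
        }
        z, sign = _combine(per_sp.values())
        g.add_node(group, scores=per_sp, z=z, sign=sign)

    n_self = 0
    n_edge_unmapped = 0
    for sp, iset in interactions.items():
        for a, b, count in iset:
            ga, gb = orthology.group_of(a), orthology.group_of(b)
            if ga is None or gb is None or ga not in g or gb not in g:
                n_edge_unmapped += 1
                continue
            if ga == gb:
                n_self += 1
                if not allow_self_loops:
                    continue
            if g.has_edge(ga, gb):
                g.edges[ga, gb]["weight"] += count
            else:
                g.add_edge(ga, gb, weight=float(count))
    if n_self:
        log.info("dropped %d orthogroup-internal interactions (self-loops)", n_self)
    if n_edge_unmapped:
        log.info(
            "skipped %d interactions with unmapped or unscored endpoints",
            n_edge_unmapped,
        )

    if g.number_of_nodes() == 0:
        raise ValueError(
            "joint network is empty: no orthogroup has a scored member gene"
        )
    return OrthogroupNetwork(g, species)
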