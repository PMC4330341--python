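"""Network null models and a synthetic cross-species fixture generator.

Two randomizations probe whether found modules reflect real signal:

* :func:`shuffle_expression` permutes each species' node scores across the
  network, keeping the topology bit-identical;
* :func:`switch_edges` performs degree-preserving double-edge swaps
  (a-b, c-d -> a-d, c-b), keeping every node's degree and the edge count
  while scrambling the wiring.

:func:`generate_fixture` builds a scored two-species orthogroup network
with planted activated modules of known pattern (conserved /
species-specific / opposite regulation), providing ground truth for
recovery and conservation-call benchmarks.  :func:`write_fixture` emits
the fixture in the standard input formats (expression TSVs, per-species
edge lists, orthology map, GMT, truth JSON) so the full file-based
pipeline can be exercised end to end.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .data import GeneSetCollection, OrthologyMap
from .network import OrthogroupNetwork

log = logging.getLogger(__name__)

__all__ = [
    "shuffle_expression",
    "switch_edges",
    "PlantedModuleSpec",
    "PlantedTruth",
    "generate_fixture",
    "generate_temporal_fixture",
    "write_fixture",
]

PATTERNS = ("conserved", "species_a", "species_b", "opposite")

# Control samples are emitted with mean 0 and sample SD exactly 1 so that a
# gene's node score recomputed from the files equals the generated z.
_CONTROL_SAMPLES = (-math.sqrt(0.5), math.sqrt(0.5))


# ------------------------------------------------------------- null models
def shuffle_expression(network: OrthogroupNetwork, rng_seed: int = 0) -> OrthogroupNetwork:
    """Permute per-species node scores across nodes; topology untouched.

    Each species' signed scores are permuted independently among the nodes
    that carry a score for that species, so the per-species score multiset
    is preserved exactly.  Combined scores are recomputed.
    """
    rng = np.random.default_rng(int(rng_seed))
    shuffled: dict[str, dict[str, float]] = {}
    for sp in network.species:
        carriers = [n for n in network.nodes if sp in network.graph.nodes[n]["scores"]]
        values = [network.graph.nodes[n]["scores"][sp] for n in carriers]
        perm = rng.permutation(len(carriers))
        shuffled[sp] = {n: values[perm[i]] for i, n in enumerate(carriers)}
    return OrthogroupNetwork.from_scores(
        (
            (u, v, d["weight"])
            for u, v, d in network.graph.edges(data=True)
        ),
        shuffled,
        network.species,
    )


def switch_edges(
    network: OrthogroupNetwork,
    n_swaps: Optional[int] = None,
    rng_seed: int = 0,
) -> OrthogroupNetwork:
    """Degree-preserving rewiring by repeated double-edge swaps.

    Picks two edges a-b and c-d and rewires them to a-d and c-b, rejecting
    swaps that would create self-loops or multi-edges (the standard
    degree-preserving MCMC).  Edge weights travel with the rewired edges.
    Defaults to 10x the edge count attempted swaps.
    """
    out = network.copy()
    g = out.graph
    edges = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
    if len(edges) < 2:
        log.warning("fewer than two edges: returning the network unchanged")
        return out
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    rng = np.random.default_rng(int(rng_seed))
    for _ in range(int(n_swaps)):
        i, j = rng.integers(len(edges), size=2)
        if i == j:
            continue
        a, b, w1 = edges[i]
        c, d, w2 = edges[j]
        # a-b, c-d -> a-d, c-b
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, weight=w1)
        g.add_edge(c, b, weight=w2)
        edges[i] = (a, d, w1)
        edges[j] = (c, b, w2)
    return out


# --------------------------------------------------------------- generator
@dataclass
class PlantedModuleSpec:
    """Recipe for one planted module."""

    size: int
    pattern: str = "conserved"
    effect: float = 3.0
    active_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.size < 2:
            raise ValueError("planted modules need >= 2 nodes")
        if not (0.0 < self.active_fraction <= 1.0):
            raise ValueError("active_fraction must be in (0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a generated fixture."""

    modules: list[tuple[str, ...]]
    patterns: list[str]
    effects: list[float]
    noise_sd: float
    rng_seed: int
    schedule: Optional[dict[str, list[list[str]]]] = None  # time -> active nodes per module

    def expected_category(self, index: int) -> str:
        return {"conserved": "CM", "species_a": "SP", "species_b": "SP",
                "opposite": "OP"}[self.patterns[index]]

    def to_dict(self) -> dict:
        return {
            "modules": [list(m) for m in self.modules],
            "patterns": self.patterns,
            "effects": self.effects,
            "noise_sd": self.noise_sd,
            "rng_seed": self.rng_seed,
            "schedule": self.schedule,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PlantedTruth":
        return cls(
            modules=[tuple(m) for m in payload["modules"]],
            patterns=list(payload["patterns"]),
            effects=[float(e) for e in payload["effects"]],
            noise_sd=float(payload["noise_sd"]),
            rng_seed=int(payload["rng_seed"]),
            schedule=payload.get("schedule"),
        )


def _background_graph(
    n_nodes: int, model: str, mean_degree: float, rng: np.random.Generator
) -> nx.Graph:
    seed = int(rng.integers(2**31 - 1))
    if model == "er":
        p = min(1.0, mean_degree / max(1, n_nodes - 1))
        return nx.gnp_random_graph(n_nodes, p, seed=seed)
    if model == "pa":
        m = max(1, round(mean_degree / 2))
        return nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    raise ValueError(f"unknown background model {model!r}")


def _planted_scores(
    pattern: str, effect: float, direction: int, noise_sd: float, rng: np.random.Generator
) -> tuple[float, float]:
    noise = rng.normal(0.0, noise_sd, size=2)
    base = direction * effect
    if pattern == "conserved":
        return base + noise[0], base + noise[1]
    if pattern == "species_a":
        return base + noise[0], float(rng.normal())
    if pattern == "species_b":
        return float(rng.normal()), base + noise[1]
    # opposite regulation
    return base + noise[0], -base + noise[1]


def generate_fixture(
    n_nodes: int = 200,
    planted: Sequence[PlantedModuleSpec] = (
        PlantedModuleSpec(8, "conserved", 3.0),
        PlantedModuleSpec(8, "species_a", 3.0),
        PlantedModuleSpec(8, "opposite", 3.0),
    ),
    *,
    noise_sd: float = 0.5,
    background_model: str = "er",
    mean_degree: float = 6.0,
    internal_p: float = 0.5,
    internal_weight: float = 3.0,
    species: tuple[str, str] = ("mouse", "macaque"),
    rng_seed: int = 0,
) -> tuple[OrthogroupNetwork, PlantedTruth]:
    """Generate a scored two-species network with planted modules.

    Background: an Erdos-Renyi (or preferential-attachment) graph with the
    requested mean degree, unit edge weights, and per-species scores drawn
    from a standard normal.  Each planted module occupies a disjoint node
    block made connected by a random spanning tree plus extra internal
    edges at probability ``internal_p``; internal edges carry
    ``internal_weight`` total evidence (emulating support seen in both
    species).  Planted node scores follow the module's pattern at its
    effect size plus N(0, noise_sd) noise; a module's ``active_fraction``
    controls how many members carry the effect (the rest stay at
    background scores, emulating nodes recruited through interactions
    rather than expression).  Background edges that would directly bridge
    two distinct planted blocks are removed: adjacent activated blocks
    would form a single active region, leaving the planted truth
    ill-defined.
    """
    total_planted = sum(p.size for p in planted)
    if total_planted > n_nodes:
        raise ValueError(
            f"cannot plant {total_planted} module nodes in {n_nodes} nodes"
        )
    rng = np.random.default_rng(int(rng_seed))
    width = len(str(max(n_nodes, 1)))
    names = [f"OG{i:0{width}d}" for i in range(n_nodes)]

    g_raw = _background_graph(n_nodes, background_model, mean_degree, rng)
    g = nx.Graph()
    g.add_nodes_from(names)
    for u, v in g_raw.edges:
        g.add_edge(names[u], names[v], weight=1.0)

    # planted blocks: disjoint, deterministic positions at the front
    blocks: list[list[str]] = []
    cursor = 0
    for spec in planted:
        block = names[cursor : cursor + spec.size]
        cursor += spec.size
        blocks.append(block)
    # distinct planted modules must not touch directly, otherwise the truth
    # is ill-defined (two adjacent activated blocks are one active region)
    block_of = {n: i for i, b in enumerate(blocks) for n in b}
    for u, v in list(g.edges):
        bu, bv = block_of.get(u), block_of.get(v)
        if bu is not None and bv is not None and bu != bv:
            g.remove_edge(u, v)
    for spec, block in zip(planted, blocks):
        # random spanning tree over the block guarantees connectivity
        order = list(rng.permutation(spec.size))
        for i in range(1, spec.size):
            u = block[order[i]]
            v = block[order[int(rng.integers(i))]]
            if g.has_edge(u, v):
                g.edges[u, v]["weight"] = float(internal_weight)
            else:
                g.add_edge(u, v, weight=float(internal_weight))
        for i in range(spec.size):
            for j in range(i + 1, spec.size):
                u, v = block[i], block[j]
                if not g.has_edge(u, v) and rng.random() < internal_p:
                    g.add_edge(u, v, weight=float(internal_weight))

    sa, sb = species
    scores_a = {n: float(v) for n, v in zip(names, rng.normal(size=n_nodes))}
    scores_b = {n: float(v) for n, v in zip(names, rng.normal(size=n_nodes))}
    directions: list[int] = []
    for spec, block in zip(planted, blocks):
        direction = 1 if rng.random() < 0.5 else -1
        directions.append(direction)
        n_active = max(2, round(spec.active_fraction * spec.size))
        for i, node in enumerate(block):
            if i >= n_active:
                continue
            za, zb = _planted_scores(spec.pattern, spec.effect, direction, noise_sd, rng)
            scores_a[node] = za
            scores_b[node] = zb

    network = OrthogroupNetwork.from_scores(
        ((u, v, d["weight"]) for u, v, d in g.edges(data=True)),
        {sa: scores_a, sb: scores_b},
        species,
    )
    truth = PlantedTruth(
        modules=[tuple(b) for b in blocks],
        patterns=[p.pattern for p in planted],
        effects=[p.effect for p in planted],
        noise_sd=noise_sd,
        rng_seed=int(rng_seed),
    )
    return network, truth


def generate_temporal_fixture(
    times: Sequence[str] = ("t1", "t2", "t3"),
    n_nodes: int = 150,
    *,
    persistent_size: int = 12,
    transient_size: int = 8,
    transient_time_index: int = 1,
    effect: float = 3.0,
    noise_sd: float = 0.5,
    mean_degree: float = 6.0,
    internal_p: float = 0.5,
    internal_weight: float = 3.0,
    species: tuple[str, str] = ("mouse", "macaque"),
    rng_seed: int = 0,
) -> tuple[dict[str, OrthogroupNetwork], PlantedTruth]:
    """Per-time-point networks with one persistent and one transient module.

    All time points share one topology.  The persistent module is active
    at every time point, with an appearance schedule that grows from a
    third of its nodes at the first time point to the full set at the
    last (emulating a response that recruits genes as it develops).  The
    transient module is active at a single time point only.
    """
    if len(times) < 2:
        raise ValueError("need at least two time points")
    rng = np.random.default_rng(int(rng_seed))
    base_net, truth = generate_fixture(
        n_nodes,
        (
            PlantedModuleSpec(persistent_size, "conserved", effect),
            PlantedModuleSpec(transient_size, "conserved", effect),
        ),
        noise_sd=noise_sd,
        background_model="er",
        mean_degree=mean_degree,
        internal_p=internal_p,
        internal_weight=internal_weight,
        species=species,
        rng_seed=int(rng.integers(2**31 - 1)),
    )
    persistent, transient = truth.modules
    n_times = len(times)
    schedule: dict[str, list[list[str]]] = {}
    for ti, t in enumerate(times):
        # persistent module grows linearly to its full size
        frac = (ti + 1) / n_times
        k = max(4, round(frac * persistent_size))
        active_p = list(persistent[:k])
        active_t = list(transient) if ti == transient_time_index else []
        schedule[t] = [active_p, active_t]

    networks: dict[str, OrthogroupNetwork] = {}
    sa, sb = species
    for ti, t in enumerate(times):
        scores_a: dict[str, float] = {}
        scores_b: dict[str, float] = {}
        active = set(schedule[t][0]) | set(schedule[t][1])
        for node in base_net.nodes:
            if node in active:
                za, zb = _planted_scores("conserved", effect, 1, noise_sd, rng)
            else:
                za, zb = float(rng.normal()), float(rng.normal())
            scores_a[node] = za
            scores_b[node] = zb
        networks[t] = OrthogroupNetwork.from_scores(
            (
                (u, v, d["weight"])
                for u, v, d in base_net.graph.edges(data=True)
            ),
            {sa: scores_a, sb: scores_b},
            species,
        )
    truth.schedule = {t: [list(a), list(b)] for t, (a, b) in schedule.items()}
    return networks, truth


# ------------------------------------------------------------ file emission
def _gene(node: str, species: str) -> str:
    return f"{node.lower()}_{species}"


def write_fixture(
    network: OrthogroupNetwork,
    truth: PlantedTruth,
    outdir,
    *,
    n_decoy_sets: int = 5,
    decoy_size: int = 10,
) -> dict[str, Path]:
    """Emit a fixture as standard input files; returns the path map.

    Each orthogroup gets one gene per species.  Expression files are
    constructed so that re-scoring them reproduces the generated node
    scores exactly: controls have mean 0 and sample SD 1, treatments are
    constant at the target z.  Joint edge weights w are split into
    ceil(w/2) evidence lines for the first species and floor(w/2) for the
    second (a weight-1 edge appears in the first species only).  The GMT
    holds the planted modules' gene sets plus decoy sets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sa, sb = network.species[:2]
    rng = np.random.default_rng(truth.rng_seed + 104729)

    paths: dict[str, Path] = {}
    # expression: treatment + control per species
    for sp in (sa, sb):
        treat_lines = ["gene\ts1\ts2"]
        ctrl_lines = ["gene\ts1\ts2"]
        for node in network.nodes:
            z = network.species_score(node, sp)
            if z is None:
                continue
            gene = _gene(node, sp)
            treat_lines.append(f"{gene}\t{z:.10g}\t{z:.10g}")
            ctrl_lines.append(
                f"{gene}\t{_CONTROL_SAMPLES[0]:.10g}\t{_CONTROL_SAMPLES[1]:.10g}"
            )
        paths[f"expr_{sp}_treatment"] = outdir / f"expr_{sp}_treatment.tsv"
        paths[f"expr_{sp}_control"] = outdir / f"expr_{sp}_control.tsv"
        paths[f"expr_{sp}_treatment"].write_text("\n".join(treat_lines) + "\n")
        paths[f"expr_{sp}_control"].write_text("\n".join(ctrl_lines) + "\n")

    # per-species edge lists: evidence lines sum to the joint weight
    lines_a: list[str] = []
    lines_b: list[str] = []
    for u, v, d in sorted(network.graph.edges(data=True)):
        w = int(round(d["weight"]))
        na = (w + 1) // 2
        for _ in range(na):
            lines_a.append(f"{_gene(u, sa)}\t{_gene(v, sa)}")
        for _ in range(w - na):
            lines_b.append(f"{_gene(u, sb)}\t{_gene(v, sb)}")
    paths[f"edges_{sa}"] = outdir / f"edges_{sa}.tsv"
    paths[f"edges_{sb}"] = outdir / f"edges_{sb}.tsv"
    paths[f"edges_{sa}"].write_text("\n".join(lines_a) + "\n" if lines_a else "")
    paths[f"edges_{sb}"].write_text("\n".join(lines_b) + "\n" if lines_b else "")

    # orthology: one gene per species per orthogroup
    ortho_lines = []
    for node in network.nodes:
        ortho_lines.append(f"{_gene(node, sa)}\t{node}")
        ortho_lines.append(f"{_gene(node, sb)}\t{node}")
    paths["orthology"] = outdir / "orthology.tsv"
    paths["orthology"].write_text("\n".join(ortho_lines) + "\n")

    # gene sets: planted modules (union of both species' genes) + decoys
    gmt_lines = []
    for i, block in enumerate(truth.modules):
        genes = [_gene(n, sp) for n in block for sp in (sa, sb)]
        gmt_lines.append(
            "\t".join([f"planted_{i + 1}", truth.patterns[i]] + sorted(genes))
        )
    all_nodes = network.nodes
    for i in range(n_decoy_sets):
        pick = rng.choice(len(all_nodes), size=min(decoy_size, len(all_nodes)), replace=False)
        genes = [_gene(all_nodes[j], sp) for j in sorted(pick) for sp in (sa, sb)]
        gmt_lines.append("\t".join([f"decoy_{i + 1}", "decoy"] + sorted(genes)))
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    paths["gene_sets"].write_text("\n".join(gmt_lines) + "\n")

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n")
    return paths
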