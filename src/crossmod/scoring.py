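"""Node scores, background calibration, and the module objective.

A gene's node score is the z-value of its mean treatment expression under a
Gaussian fitted to the control samples:

    z = (mean(treatment) - mean(control)) / SD(control)

Orthogroup node scores in the joint network are combined from member genes
(see :mod:`crossmod.network`).  A candidate module j of M nodes is scored as

    S_j = (1/sigma_Z) * sum_i (Z_i - beta_Z * mu_Z) / sqrt(M)
          + W * (sum_h E_h - mu_E(M)) / sigma_E(M)

where (mu_Z, sigma_Z) are the mean/SD of combined node scores over the
whole network, beta_Z shrinks the per-node centring (beta_Z > 1 yields
fewer positive-scoring nodes, hence smaller modules), E_h are the evidence
weights of edges internal to the module, and (mu_E(M), sigma_E(M)) is the
size-conditional edge-weight background estimated by sampling random
connected node subsets of size M.  W weighs connectivity against
activation; W = 0 reduces to the classic node-only objective.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .network import OrthogroupNetwork

log = logging.getLogger(__name__)

__all__ = [
    "node_score",
    "score_genes",
    "fit_node_background",
    "sample_connected_subset",
    "calibrate_edge_background",
    "BackgroundStats",
    "module_node_component",
    "module_score",
]

#: replacement magnitude for the edge term when sigma_E(M) is degenerate
#: (zero) and the observed internal weight deviates from mu_E(M)
DEGENERATE_EDGE_CAP = 1e6


class EdgeBackgroundUnavailable(RuntimeError):
    """No edge background for the requested module size; calibrate first."""


# ------------------------------------------------------------- node scoring
def node_score(
    treatment_values: Sequence[float],
    control_values: Sequence[float],
    *,
    control_sd: Optional[float] = None,
    sd_floor: Optional[float] = None,
) -> float:
    """Signed differential-expression z of a gene.

    ``control_sd`` supplies a global control SD (then a single control
    sample suffices); otherwise at least two control samples are required.
    ``sd_floor`` replaces a zero control SD instead of raising.
    """
    t = np.asarray(treatment_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    t = t[~np.isnan(t)]
    c = c[~np.isnan(c)]
    if t.size == 0 or c.size == 0:
        raise ValueError("node_score needs non-missing treatment and control values")
    if control_sd is None:
        if c.size < 2:
            raise ValueError(
                "need >= 2 control samples to estimate the control SD "
                "(or pass control_sd)"
            )
        control_sd = float(np.std(c, ddof=1))
    if control_sd <= 0:
        if sd_floor is not None and sd_floor > 0:
            control_sd = sd_floor
        else:
            raise ValueError("control SD is zero; configure sd_floor to proceed")
    return float((t.mean() - c.mean()) / control_sd)


def score_genes(treatment, control, *, sd_floor: Optional[float] = None) -> dict[str, float]:
    """Per-gene node scores for two aligned expression tables.

    Treatment samples are averaged over the table's whole time window first
    (columns are samples/time points).  Genes missing from either table or
    with no finite values are skipped.
    """
    scores: dict[str, float] = {}
    common = [g for g in treatment.genes if g in set(control.genes)]
    for gene in common:
        t = treatment.values.loc[gene].to_numpy(dtype=float)
        c = control.values.loc[gene].to_numpy(dtype=float)
        if np.isnan(t).all() or np.isnan(c).all():
            continue
        try:
            scores[gene] = node_score(t, c, sd_floor=sd_floor)
        except ValueError:
            continue
    return scores


# ----------------------------------------------------------- node background
def fit_node_background(network: OrthogroupNetwork) -> tuple[float, float]:
    """Sample mean and SD of combined node scores over the network."""
    z = network.score_array()
    if z.size < 2:
        raise ValueError("need at least two nodes to fit the node background")
    mu = float(z.mean())
    sigma = float(z.std(ddof=1))
    if sigma == 0:
        raise ValueError("all node scores identical: sigma_Z would be zero")
    return mu, sigma


# ----------------------------------------------------------- edge background
def sample_connected_subset(
    network: OrthogroupNetwork, size: int, rng: np.random.Generator
) -> list[str]:
    """One uniform-seeded random connected node subset of ``size`` nodes.

    A seed node is drawn uniformly among nodes whose component can host the
    subset, then the subset grows by repeated uniform choice among frontier
    neighbours.  Raises ``EdgeBackgroundUnavailable`` if no component is
    large enough.
    """
    import networkx as nx

    g = network.graph
    if size < 1:
        raise ValueError("subset size must be >= 1")
    eligible = [
        n
        for comp in nx.connected_components(g)
        if len(comp) >= size
        for n in sorted(comp)
    ]
    if not eligible:
        raise EdgeBackgroundUnavailable(
            f"no connected component with >= {size} nodes"
        )
    seed = eligible[rng.integers(len(eligible))]
    members = [seed]
    member_set = {seed}
    frontier: list[str] = []
    frontier_set: set[str] = set()
    for nb in g[seed]:
        if nb not in member_set and nb not in frontier_set:
            frontier.append(nb)
            frontier_set.add(nb)
    while len(members) < size:
        pick = frontier.pop(rng.integers(len(frontier)))
        frontier_set.discard(pick)
        members.append(pick)
        member_set.add(pick)
        for nb in g[pick]:
            if nb not in member_set and nb not in frontier_set:
                frontier.append(nb)
                frontier_set.add(nb)
    return members


def calibrate_edge_background(
    network: OrthogroupNetwork,
    sizes: Iterable[int],
    n_samples: int = 1000,
    rng_seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Size-conditional background of internal edge-weight sums.

    For each requested module size M, draws ``n_samples`` random connected
    subsets and records the mean and sample SD of their summed internal
    edge weights.  M = 1 is (0, 0) by definition.  Each size uses its own
    RNG stream derived from ``(rng_seed, M)``, so calibrating sizes lazily
    or out of order yields identical numbers.
    """
    out: dict[int, tuple[float, float]] = {}
    for size in sizes:
        if size == 1:
            out[1] = (0.0, 0.0)
            continue
        rng = np.random.default_rng([int(rng_seed), int(size)])
        sums = np.empty(n_samples)
        for i in range(n_samples):
            subset = sample_connected_subset(network, size, rng)
            sums[i] = network.internal_edge_sum(subset)
        out[size] = (float(sums.mean()), float(sums.std(ddof=1)))
    return out


@dataclass
class BackgroundStats:
    """Calibrated background parameters for the module objective.

    ``edge_bg`` maps module size M to (mu_E(M), sigma_E(M)); entries are
    filled lazily up to ``max_module_size`` as sizes are first scored.
    The whole object serializes to JSON so a search can be reproduced
    without recalibration.
    """

    mu_z: float
    sigma_z: float
    beta: float = 1.0
    edge_weight: float = 0.5
    n_bg_samples: int = 1000
    rng_seed: int = 0
    max_module_size: int = 150
    edge_bg: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_z <= 0:
            raise ValueError("sigma_z must be positive")
        self.edge_bg = {int(k): (float(v[0]), float(v[1])) for k, v in self.edge_bg.items()}
        self.edge_bg.setdefault(1, (0.0, 0.0))

    def edge_stats(
        self, size: int, network: Optional[OrthogroupNetwork] = None
    ) -> tuple[float, float]:
        """(mu_E, sigma_E) for module size ``size``; computed on demand."""
        if size in self.edge_bg:
            return self.edge_bg[size]
        if network is None:
            raise EdgeBackgroundUnavailable(
                f"edge background for module size {size} not calibrated; "
                "run calibrate_edge_background or pass the network"
            )
        if size > self.max_module_size:
            raise EdgeBackgroundUnavailable(
                f"module size {size} exceeds max_module_size={self.max_module_size}"
            )
        stats = calibrate_edge_background(
            network, [size], n_samples=self.n_bg_samples, rng_seed=self.rng_seed
        )
        self.edge_bg.update(stats)
        return self.edge_bg[size]

    # -- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mu_z": self.mu_z,
            "sigma_z": self.sigma_z,
            "beta": self.beta,
            "edge_weight": self.edge_weight,
            "n_bg_samples": self.n_bg_samples,
            "rng_seed": self.rng_seed,
            "max_module_size": self.max_module_size,
            "edge_bg": {str(k): list(v) for k, v in sorted(self.edge_bg.items())},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BackgroundStats":
        payload = dict(payload)
        payload["edge_bg"] = {
            int(k): tuple(v) for k, v in payload.get("edge_bg", {}).items()
        }
        return cls(**payload)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "BackgroundStats":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_network(
        cls,
        network: OrthogroupNetwork,
        *,
        beta: float = 1.0,
        edge_weight: float = 0.5,
        n_bg_samples: int = 1000,
        rng_seed: int = 0,
        max_module_size: int = 150,
        precalibrate_sizes: Optional[Iterable[int]] = None,
    ) -> "BackgroundStats":
        mu, sigma = fit_node_background(network)
        bg = cls(
            mu_z=mu,
            sigma_z=sigma,
            beta=beta,
            edge_weight=edge_weight,
            n_bg_samples=n_bg_samples,
            rng_seed=rng_seed,
            max_module_size=max_module_size,
        )
        if precalibrate_sizes is not None:
            bg.edge_bg.update(
                calibrate_edge_background(
                    network, precalibrate_sizes, n_samples=n_bg_samples, rng_seed=rng_seed
                )
            )
        return bg


# ------------------------------------------------------------ the objective
def module_node_component(node_scores: Sequence[float], bg: BackgroundStats) -> float:
    """Node part of the objective: centred, size-normalised score sum."""
    z = np.asarray(node_scores, dtype=float)
    if z.size == 0:
        raise ValueError("module has no nodes")
    m = z.size
    return float((z.sum() - m * bg.beta * bg.mu_z) / (bg.sigma_z * math.sqrt(m)))


def edge_component(
    internal_sum: float, size: int, bg: BackgroundStats,
    network: Optional[OrthogroupNetwork] = None,
) -> float:
    """Edge part of the objective (without the W weight)."""
    if size <= 1:
        return 0.0
    mu_e, sigma_e = bg.edge_stats(size, network)
    dev = internal_sum - mu_e
    if sigma_e == 0:
        if dev == 0:
            return 0.0
        warnings.warn(
            f"sigma_E({size}) is zero; capping the edge term",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.copysign(DEGENERATE_EDGE_CAP, dev)
    return dev / sigma_e


def module_score(
    module_nodes: Iterable[str],
    network: OrthogroupNetwork,
    bg: BackgroundStats,
    *,
    lazy_calibrate: bool = True,
) -> float:
    """Objective value S_j of a candidate module.

    With ``lazy_calibrate`` (default) a missing edge background for the
    module's size is computed on the spot from ``network``; otherwise an
    :class:`EdgeBackgroundUnavailable` error directs the user to calibrate.
    """
    nodes = list(module_nodes)
    if not nodes:
        raise ValueError("module has no nodes")
    z = [network.combined_score(n) for n in nodes]
    score = module_node_component(z, bg)
    if bg.edge_weight != 0 and len(nodes) > 1:
        internal = network.internal_edge_sum(nodes)
        score += bg.edge_weight * edge_component(
            internal, len(nodes), bg, network if lazy_calibrate else None
        )
    return score
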