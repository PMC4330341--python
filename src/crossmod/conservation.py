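"""Cross-species divergence and activation statistics with empirical calls.

For a module of M nodes with per-species signed scores Z_iA, Z_iB:

    Diff(S_j)      = sum_i |Z_iA - Z_iB| / sqrt(M)      (L1 divergence)
    Active(S_j, X) = sum_i |Z_iX|        / sqrt(M)      (per-species activation)

Both are compared against the same statistics on random size-M node subsets
drawn (without a connectivity requirement) from the pool of nodes belonging
to any final module.  ``diff_pct`` / ``active_pct`` are the fractions of
random subsets whose statistic is >= the observed one, so SMALL percentiles
mean EXTREME observed values.  Categories:

    CM (conserved)            diff_pct > 0.95
    OP (opposite regulation)  diff_pct < 0.05 and high activation in both
                              species (active_pct < 0.05 in both)
    SP (species-specific)     diff_pct < 0.05 and high activation in
                              exactly one species
    unclassified              everything else

A node missing a score in one species contributes |Z_present - 0| to Diff
(logged per module).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .data import Module
from .network import OrthogroupNetwork

log = logging.getLogger(__name__)

__all__ = [
    "ConservationCall",
    "diff_stat",
    "active_stat",
    "null_percentiles",
    "classify",
    "assess_modules",
]


@dataclass
class ConservationCall:
    """Divergence/activation statistics and the resulting category."""

    diff: float
    active: dict[str, float]
    diff_pct: float
    active_pct: dict[str, float]
    category: str
    n_random: int = 10000
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "diff": self.diff,
            "active": dict(self.active),
            "diff_pct": self.diff_pct,
            "active_pct": dict(self.active_pct),
            "category": self.category,
            "n_random": self.n_random,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ConservationCall":
        return cls(**payload)


def _species_vector(
    network: OrthogroupNetwork, nodes: Sequence[str], species: str
) -> np.ndarray:
    if species not in network.species:
        raise ValueError(f"species {species!r} absent from network {network.species}")
    vals = []
    n_missing = 0
    for n in nodes:
        v = network.species_score(n, species)
        if v is None:
            n_missing += 1
            v = 0.0
        vals.append(v)
    if n_missing:
        log.debug("%d/%d nodes missing a %s score (treated as 0)", n_missing, len(nodes), species)
    return np.asarray(vals, dtype=float)


def diff_stat(
    module_nodes: Iterable[str],
    network: OrthogroupNetwork,
    species_a: str,
    species_b: str,
) -> float:
    """L1 cross-species divergence of a module, normalised by sqrt(M)."""
    nodes = list(module_nodes)
    if not nodes:
        raise ValueError("module has no nodes")
    za = _species_vector(network, nodes, species_a)
    zb = _species_vector(network, nodes, species_b)
    return float(np.abs(za - zb).sum() / math.sqrt(len(nodes)))


def active_stat(
    module_nodes: Iterable[str], network: OrthogroupNetwork, species: str
) -> float:
    """Per-species absolute activation of a module, normalised by sqrt(M)."""
    nodes = list(module_nodes)
    if not nodes:
        raise ValueError("module has no nodes")
    z = _species_vector(network, nodes, species)
    return float(np.abs(z).sum() / math.sqrt(len(nodes)))


def null_percentiles(
    module_nodes: Iterable[str],
    network: OrthogroupNetwork,
    module_node_pool: Sequence[str],
    n_random: int = 10000,
    rng_seed: int = 0,
) -> tuple[float, dict[str, float]]:
    """Empirical upper-tail percentiles of Diff and Active per species.

    Draws ``n_random`` uniform size-M node subsets (connectivity NOT
    required) from ``module_node_pool`` and reports the fraction of draws
    whose statistic is >= the observed one (ties count as >=).
    """
    nodes = list(module_nodes)
    pool = list(module_node_pool)
    m = len(nodes)
    if len(pool) < m:
        raise ValueError(
            f"pool of {len(pool)} nodes cannot host modules of size {m}"
        )
    if len(network.species) < 2:
        raise ValueError("need at least two species for the divergence null")
    sa, sb = network.species[0], network.species[1]

    obs_diff = diff_stat(nodes, network, sa, sb)
    obs_active = {sp: active_stat(nodes, network, sp) for sp in network.species}

    pool_a = _species_vector(network, pool, sa)
    pool_b = _species_vector(network, pool, sb)
    per_node_diff = np.abs(pool_a - pool_b)
    per_node_active = {
        sp: np.abs(_species_vector(network, pool, sp)) for sp in network.species
    }

    rng = np.random.default_rng([int(rng_seed) & 0x7FFFFFFF, m])
    # uniform random M-subsets per row via the random-permutation trick
    idx = np.argsort(rng.random((n_random, len(pool))), axis=1)[:, :m]
    sqrt_m = math.sqrt(m)

    diff_null = per_node_diff[idx].sum(axis=1) / sqrt_m
    diff_pct = float(np.mean(diff_null >= obs_diff))
    active_pct = {}
    for sp in network.species:
        null = per_node_active[sp][idx].sum(axis=1) / sqrt_m
        active_pct[sp] = float(np.mean(null >= obs_active[sp]))
    return diff_pct, active_pct


def classify(
    diff_pct: float, active_pct: Mapping[str, float], alpha: float = 0.05
) -> str:
    """Assign the CM/SP/OP/unclassified category from percentiles."""
    if diff_pct > 1 - alpha:
        return "CM"
    if diff_pct < alpha:
        n_active = sum(1 for p in active_pct.values() if p < alpha)
        if n_active == len(active_pct) and n_active >= 2:
            return "OP"
        if n_active == 1:
            return "SP"
    return "unclassified"


def assess_modules(
    modules: Sequence[Module],
    network: OrthogroupNetwork,
    *,
    n_random: int = 10000,
    rng_seed: int = 0,
    alpha: float = 0.05,
    pool: Optional[Sequence[str]] = None,
) -> list[Module]:
    """Attach a :class:`ConservationCall` to every module (in place).

    The randomization pool defaults to the union of all module nodes, the
    natural reference for "how divergent is a typical module-sized set of
    module genes".
    """
    if pool is None:
        pool = sorted({n for m in modules for n in m.nodes})
    sa, sb = network.species[0], network.species[1]
    for i, mod in enumerate(modules):
        diff_pct, active_pct = null_percentiles(
            mod.nodes, network, pool, n_random=n_random, rng_seed=rng_seed + i
        )
        mod.conservation = ConservationCall(
            diff=diff_stat(mod.nodes, network, sa, sb),
            active={sp: active_stat(mod.nodes, network, sp) for sp in network.species},
            diff_pct=diff_pct,
            active_pct=active_pct,
            category=classify(diff_pct, active_pct, alpha=alpha),
            n_random=n_random,
            rng_seed=rng_seed + i,
        )
    return list(modules)
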