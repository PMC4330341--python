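"""Gene-set enrichment of modules and the (W, beta_Z) parameter grid.

Modules live in orthogroup space; for enrichment each module is expanded to
the union of its member genes across species (annotation namespaces for the
compared species are combined).  Per module, each gene set is tested with
an upper-tail hypergeometric p-value; multiple testing across the sets
tested for one module is handled by Bonferroni (default) or
Benjamini-Hochberg.

Because no gold standard of condition-specific modules usually exists, the
edge weight W and the centring parameter beta_Z are chosen by a grid that
scores each candidate setting by three generic criteria: (i) the
percentage of modules carrying at least one uniquely enriched set (a set
significant in that module and no other), (ii) the percentage of
differentially expressed nodes among module nodes, and (iii) the total
module count.  The recommended point maximises the within-grid rank sum of
(i) and (ii), breaking ties toward fewer modules.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import GeneSetCollection, Module, OrthologyMap
from .network import OrthogroupNetwork
from .scoring import BackgroundStats
from .search import SearchConfig, run_search

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "module_genes",
    "enrich_module",
    "unique_enrichment",
    "GridPoint",
    "parameter_grid",
    "recommend_parameters",
]


@dataclass
class EnrichmentResult:
    module_id: str
    set_name: str
    overlap: int
    pvalue: float
    corrected_p: float
    method: str
    significant: bool


def module_genes(module: Module, orthology: OrthologyMap) -> set[str]:
    """Union of member genes (all species) of a module's orthogroups."""
    groups = orthology.groups()
    out: set[str] = set()
    for node in module.nodes:
        out.update(groups.get(node, []))
    return out


def enrich_module(
    genes: Iterable[str],
    collection: GeneSetCollection,
    universe_size: int,
    *,
    module_id: str = "",
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of one module's genes against a collection.

    ``universe_size`` is the size of the background gene population (by
    default callers use all genes of the joint network's orthogroups).
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    gene_set = set(genes)
    names = sorted(collection.names())
    pvals = []
    overlaps = []
    for name in names:
        members = collection[name]
        k = len(gene_set & members)
        overlaps.append(k)
        pvals.append(
            float(hypergeom.sf(k - 1, universe_size, len(members), len(gene_set)))
        )
    pvals_arr = np.asarray(pvals)
    if correction == "bonferroni":
        corrected = np.minimum(pvals_arr * len(names), 1.0)
        significant = corrected < alpha
    else:
        significant, corrected, _, _ = multipletests(
            pvals_arr, alpha=alpha, method="fdr_bh"
        )
    return [
        EnrichmentResult(
            module_id=module_id,
            set_name=name,
            overlap=overlaps[i],
            pvalue=pvals[i],
            corrected_p=float(corrected[i]),
            method=correction,
            significant=bool(significant[i]),
        )
        for i, name in enumerate(names)
    ]


def unique_enrichment(
    results: Iterable[EnrichmentResult],
) -> dict[str, list[str]]:
    """Per-module lists of uniquely enriched set names.

    A set is uniquely enriched for a module iff it is significant there
    and in no other module.  Modules without significant sets map to [].
    """
    sig_modules: dict[str, set[str]] = {}
    module_ids: list[str] = []
    for r in results:
        if r.module_id not in module_ids:
            module_ids.append(r.module_id)
        if r.significant:
            sig_modules.setdefault(r.set_name, set()).add(r.module_id)
    out: dict[str, list[str]] = {mid: [] for mid in module_ids}
    for set_name, mods in sorted(sig_modules.items()):
        if len(mods) == 1:
            out[next(iter(mods))].append(set_name)
    return out


@dataclass
class GridPoint:
    """One (W, beta_Z) evaluation of the three selection criteria."""

    w: float
    beta: float
    pct_unique_enriched: float  # criterion (i), percent
    pct_de_nodes: float         # criterion (ii), percent
    n_modules: int              # criterion (iii)
    digest: str = ""
    failed: bool = False


def _de_fraction(network: OrthogroupNetwork, nodes: Iterable[str], threshold: float) -> float:
    """Fraction of nodes whose max-scaled combined score exceeds threshold.

    Scores are scaled to [0, 1] by the network-wide maximum so the rule
    matches the "scaled fold change > 0.25" convention.
    """
    nodes = list(nodes)
    if not nodes:
        return 0.0
    zmax = float(network.score_array().max())
    if zmax == 0:
        return 0.0
    return float(
        np.mean([network.combined_score(n) / zmax > threshold for n in nodes])
    )


def _modules_digest(modules: Sequence[Module]) -> str:
    payload = ";".join(",".join(m.nodes) for m in sorted(modules, key=lambda m: m.nodes))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def parameter_grid(
    network: OrthogroupNetwork,
    bg_template: BackgroundStats,
    w_values: Sequence[float],
    beta_values: Sequence[float],
    collection: GeneSetCollection,
    orthology: OrthologyMap,
    *,
    search_config: Optional[SearchConfig] = None,
    universe_size: Optional[int] = None,
    de_threshold: float = 0.25,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> tuple[list[GridPoint], tuple[float, float]]:
    """Evaluate the selection criteria over a (W, beta_Z) grid.

    The edge background of ``bg_template`` is shared across the grid (it
    does not depend on W or beta).  Returns all grid points plus the
    recommended (W, beta_Z).
    """
    if not w_values or not beta_values:
        raise ValueError("parameter grid must be non-empty")
    if universe_size is None:
        universe_size = sum(
            len(orthology.groups().get(n, [])) for n in network.graph.nodes
        )
    config = search_config or SearchConfig()
    points: list[GridPoint] = []
    for w in w_values:
        for beta in beta_values:
            bg = replace(bg_template, edge_weight=float(w), beta=float(beta))
            bg.edge_bg = dict(bg_template.edge_bg)
            try:
                modules = run_search(network, bg, config)
                results: list[EnrichmentResult] = []
                for m in modules:
                    results.extend(
                        enrich_module(
                            module_genes(m, orthology),
                            collection,
                            universe_size,
                            module_id=m.id,
                            correction=correction,
                            alpha=alpha,
                        )
                    )
                unique = unique_enrichment(results)
                n_mod = len(modules)
                pct_unique = (
                    100.0 * sum(1 for v in unique.values() if v) / n_mod
                    if n_mod
                    else 0.0
                )
                all_nodes = {n for m in modules for n in m.nodes}
                pct_de = 100.0 * _de_fraction(network, all_nodes, de_threshold)
                points.append(
                    GridPoint(
                        w=float(w),
                        beta=float(beta),
                        pct_unique_enriched=pct_unique,
                        pct_de_nodes=pct_de,
                        n_modules=n_mod,
                        digest=_modules_digest(modules),
                    )
                )
            except Exception as exc:  # a failed grid run is recorded, not fatal
                log.warning("grid point (W=%g, beta=%g) failed: %s", w, beta, exc)
                points.append(
                    GridPoint(w=float(w), beta=float(beta),
                              pct_unique_enriched=0.0, pct_de_nodes=0.0,
                              n_modules=0, failed=True)
                )

    best = recommend_parameters(points)
    return points, (best.w, best.beta)


def recommend_parameters(points: Sequence[GridPoint]) -> GridPoint:
    """Pick the grid point maximizing the rank sum of criteria (i) and (ii).

    Failed points are excluded; ties break toward fewer modules (criterion
    (iii)), then toward larger W and beta for determinism.
    """
    ok = [p for p in points if not p.failed]
    if not ok:
        raise RuntimeError("every grid point failed")

    def rank(values: list[float], v: float) -> float:
        # average rank (1 = worst); higher criterion value -> higher rank
        smaller = sum(1 for x in values if x < v)
        equal = sum(1 for x in values if x == v)
        return smaller + (equal + 1) / 2.0

    uniq_vals = [p.pct_unique_enriched for p in ok]
    de_vals = [p.pct_de_nodes for p in ok]
    return max(
        ok,
        key=lambda p: (
            rank(uniq_vals, p.pct_unique_enriched) + rank(de_vals, p.pct_de_nodes),
            -p.n_modules,          # tie-break: fewer modules
            p.w,
            p.beta,                # final deterministic tie-break
        ),
    )
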