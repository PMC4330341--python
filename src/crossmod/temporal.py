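"""Linking per-time-point module sets into activation cascades.

Each time point gets its own module set (searched on time-point-specific
node scores).  For every ordered pair of time points t < t' and every
module pair, the node-set overlap is tested with an upper-tail
hypergeometric test; when the test is significant at alpha in both
argument orientations the modules are declared matching and a directed
link (earlier -> later) is created.  Several early modules may match one
later module (fan-in).  Chains of links spanning the whole series mark
modules that persist through time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import hypergeom

from .data import Module

log = logging.getLogger(__name__)

__all__ = [
    "overlap_pvalue",
    "CascadeLink",
    "CascadeGraph",
    "match_time_points",
    "first_appearance_layout",
]


def overlap_pvalue(set_a: Iterable[str], set_b: Iterable[str], universe_size: int) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    P(X >= k) for k = |A n B| with population ``universe_size``, |A|
    successes and |B| draws.  Symmetric in its set arguments.
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError(
            f"universe of {universe_size} cannot contain {len(a | b)} distinct nodes"
        )
    k = len(a & b)
    return float(hypergeom.sf(k - 1, universe_size, len(a), len(b)))


@dataclass
class CascadeLink:
    """A significant reciprocal match between modules at two time points."""

    time_a: str
    module_a: str
    time_b: str
    module_b: str
    overlap: int
    pvalue: float

    def to_dict(self) -> dict:
        return {
            "time_a": self.time_a,
            "module_a": self.module_a,
            "time_b": self.time_b,
            "module_b": self.module_b,
            "overlap": self.overlap,
            "pvalue": self.pvalue,
        }


@dataclass
class CascadeGraph:
    """Time-indexed module sets plus the significant links between them."""

    times: tuple[str, ...]
    modules: dict[str, list[Module]]
    links: list[CascadeLink] = field(default_factory=list)
    universe_size: int = 0
    alpha: float = 0.01

    def module(self, time: str, module_id: str) -> Module:
        for m in self.modules[time]:
            if m.id == module_id:
                return m
        raise KeyError(f"no module {module_id!r} at time {time!r}")

    def links_into(self, time: str, module_id: str) -> list[CascadeLink]:
        return [l for l in self.links if l.time_b == time and l.module_b == module_id]

    def ancestors(self, time: str, module_id: str) -> set[tuple[str, str]]:
        """All (time, module_id) with a directed link path into the target."""
        found: set[tuple[str, str]] = set()
        stack = [(time, module_id)]
        while stack:
            t, mid = stack.pop()
            for link in self.links_into(t, mid):
                key = (link.time_a, link.module_a)
                if key not in found:
                    found.add(key)
                    stack.append(key)
        return found

    def chains(self) -> list[list[tuple[str, str]]]:
        """Maximal link paths ordered by time (consecutive link steps)."""
        succ: dict[tuple[str, str], list[tuple[str, str]]] = {}
        has_pred: set[tuple[str, str]] = set()
        nodes: set[tuple[str, str]] = set()
        for link in self.links:
            a = (link.time_a, link.module_a)
            b = (link.time_b, link.module_b)
            succ.setdefault(a, []).append(b)
            has_pred.add(b)
            nodes.update((a, b))
        starts = sorted(n for n in nodes if n not in has_pred)
        out: list[list[tuple[str, str]]] = []

        def walk(path: list[tuple[str, str]]) -> None:
            nxt = succ.get(path[-1], [])
            if not nxt:
                out.append(path)
                return
            for n in sorted(nxt):
                walk(path + [n])

        for s in starts:
            walk([s])
        return out

    def full_chains(self) -> list[list[tuple[str, str]]]:
        """Chains touching every time point of the series."""
        want = set(self.times)
        return [c for c in self.chains() if {t for t, _ in c} == want]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "times": list(self.times),
            "universe_size": self.universe_size,
            "alpha": self.alpha,
            "modules": {
                t: [{"id": m.id, "nodes": list(m.nodes), "score": m.score} for m in ms]
                for t, ms in self.modules.items()
            },
            "links": [l.to_dict() for l in self.links],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    def export_graphml(self, path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for t, ms in self.modules.items():
            for m in ms:
                g.add_node(f"{t}:{m.id}", time=t, module=m.id, size=m.size)
        for l in self.links:
            g.add_edge(
                f"{l.time_a}:{l.module_a}",
                f"{l.time_b}:{l.module_b}",
                overlap=l.overlap,
                pvalue=l.pvalue,
            )
        nx.write_graphml(g, str(path))


def match_time_points(
    module_sets: Mapping[str, Sequence[Module]],
    universe_size: int,
    *,
    alpha: float = 0.01,
    times_order: Optional[Sequence[str]] = None,
    mutual_best: bool = False,
) -> CascadeGraph:
    """Link modules across time by reciprocal hypergeometric overlap.

    Every ordered pair of time points (not only consecutive ones) is
    tested.  ``mutual_best`` additionally requires each module to be the
    other's smallest-p partner at the paired time point (a stricter notion
    of reciprocity; OFF by default, since for a fixed universe the two
    test orientations already coincide by symmetry).
    """
    times = tuple(times_order) if times_order is not None else tuple(module_sets)
    if len(times) < 2:
        log.warning("only %d time point(s): empty cascade", len(times))
        return CascadeGraph(times, {t: list(module_sets.get(t, [])) for t in times},
                            [], universe_size, alpha)

    links: list[CascadeLink] = []
    for i, ta in enumerate(times):
        for tb in times[i + 1 :]:
            mods_a, mods_b = module_sets[ta], module_sets[tb]
            pvals: dict[tuple[str, str], float] = {}
            for ma in mods_a:
                for mb in mods_b:
                    p_fwd = overlap_pvalue(ma.nodes, mb.nodes, universe_size)
                    p_rev = overlap_pvalue(mb.nodes, ma.nodes, universe_size)
                    pvals[(ma.id, mb.id)] = max(p_fwd, p_rev)
            for ma in mods_a:
                for mb in mods_b:
                    p = pvals[(ma.id, mb.id)]
                    if p >= alpha:
                        continue
                    if mutual_best:
                        best_for_a = min(pvals[(ma.id, m.id)] for m in mods_b)
                        best_for_b = min(pvals[(m.id, mb.id)] for m in mods_a)
                        if p > best_for_a or p > best_for_b:
                            continue
                    links.append(
                        CascadeLink(
                            time_a=ta,
                            module_a=ma.id,
                            time_b=tb,
                            module_b=mb.id,
                            overlap=len(set(ma.nodes) & set(mb.nodes)),
                            pvalue=p,
                        )
                    )
    return CascadeGraph(
        times, {t: list(module_sets[t]) for t in times}, links, universe_size, alpha
    )


def first_appearance_layout(
    cascade: CascadeGraph, terminal_time: str, terminal_module_id: str
) -> dict[str, str]:
    """Earliest matched time of every node of a terminal module.

    Used for the column layout of a cascade endpoint: each node of the
    terminal module is placed at the earliest time point at which it
    belonged to any matched ancestor module; nodes found in no ancestor
    stay at the terminal time.
    """
    terminal = cascade.module(terminal_time, terminal_module_id)
    order = {t: i for i, t in enumerate(cascade.times)}
    layout = {n: terminal_time for n in terminal.nodes}
    for (t, mid) in cascade.ancestors(terminal_time, terminal_module_id):
        mod = cascade.module(t, mid)
        for n in mod.nodes:
            if n in layout and order[t] < order[layout[n]]:
                layout[n] = t
    return layout
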