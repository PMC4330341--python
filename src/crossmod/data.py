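"""Core domain types: expression tables, interaction sets, orthology maps,
gene-set collections and modules.

Identifiers are plain strings.  Gene-symbol matching between species with
different capitalisation conventions (e.g. mouse Title-case vs human
UPPER-case) is handled by normalising symbols to casefolded form wherever an
:class:`OrthologyMap` with ``casefold=True`` (the default) is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "InteractionSet",
    "OrthologyMap",
    "GeneSetCollection",
    "Module",
    "canonical_pair",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered gene/node pair so (a, b) and (b, a) collapse."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ExpressionTable:
    """A genes x samples matrix of log-expression (or log-fold-change) values.

    Parameters
    ----------
    species:
        Species label, e.g. ``"mouse"``.
    condition:
        ``"treatment"`` or ``"control"`` (free-form labels are accepted).
    values:
        DataFrame indexed by gene identifier with one column per sample.
        Missing measurements are ``NaN``.
    """

    species: str
    condition: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(
                f"duplicate gene identifiers in {self.species}/{self.condition} "
                f"expression table: {dupes}"
            )
        if self.values.shape[1] < 1:
            raise ValueError("expression table needs at least one sample column")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            raise ValueError("expression values must be numeric")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_means(self) -> pd.Series:
        """Per-gene mean over samples, ignoring missing values."""
        return self.values.mean(axis=1, skipna=True)


@dataclass
class InteractionSet:
    """Undirected gene-gene interactions with evidence counts for one species.

    ``edges`` maps a canonically ordered gene pair to the number of
    independent evidence lines supporting the interaction (>= 1).
    """

    species: str
    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, a: str, b: str, count: int = 1) -> None:
        if count < 1:
            raise ValueError("evidence count must be a positive integer")
        key = canonical_pair(a, b)
        self.edges[key] = self.edges.get(key, 0) + count

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        for (a, b), c in self.edges.items():
            yield a, b, c

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out


class OrthologyMap:
    """Mapping from (species-qualified) gene identifier to orthogroup id.

    Every gene maps to at most one orthogroup; an orthogroup may hold
    several genes per species (paralogs).  Matching is case-insensitive by
    default so that mouse ``Tnf`` and human ``TNF`` resolve identically.
    """

    def __init__(self, mapping: Mapping[str, str], casefold: bool = True):
        self.casefold = casefold
        self._map: dict[str, str] = {}
        for gene, group in mapping.items():
            key = self._norm(gene)
            if key in self._map and self._map[key] != group:
                raise ValueError(
                    f"gene {gene!r} maps to more than one orthogroup "
                    f"({self._map[key]!r} and {group!r})"
                )
            self._map[key] = str(group)

    def _norm(self, gene: str) -> str:
        return gene.casefold() if self.casefold else gene

    def group_of(self, gene: str) -> Optional[str]:
        return self._map.get(self._norm(gene))

    def __contains__(self, gene: str) -> bool:
        return self._norm(gene) in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._map.items())

    def groups(self) -> dict[str, list[str]]:
        """Orthogroup id -> sorted member gene list (normalised symbols)."""
        out: dict[str, list[str]] = {}
        for gene, grp in self._map.items():
            out.setdefault(grp, []).append(gene)
        return {g: sorted(m) for g, m in out.items()}

    def member_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, grp in self._map.items():
            counts[grp] = counts.get(grp, 0) + 1
        return counts


class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Optional[Mapping[str, str]] = None,
    ):
        self._sets: dict[str, frozenset[str]] = {}
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for name, genes in sets.items():
            members = frozenset(str(g) for g in genes)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if name in self._sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            self._sets[name] = members

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def items(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self._sets.items())

    def names(self) -> list[str]:
        return list(self._sets)

    def casefolded(self) -> "GeneSetCollection":
        """Collection with all member symbols casefolded (for matching)."""
        return GeneSetCollection(
            {n: {g.casefold() for g in s} for n, s in self._sets.items()},
            self.descriptions,
        )


@dataclass
class Module:
    """A connected node subset of the joint network with its objective score.

    ``nodes`` is kept as a sorted tuple so module identity is order-free.
    ``conservation`` is attached after the divergence assessment and is a
    :class:`crossmod.conservation.ConservationCall` (kept untyped here to
    avoid an import cycle).
    """

    id: str
    nodes: tuple[str, ...]
    score: Optional[float] = None
    seed: Optional[str] = None
    time_point: Optional[str] = None
    conservation: Optional[object] = None
    trace: Optional[list] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = tuple(sorted(self.nodes))

    @property
    def size(self) -> int:
        return len(self.nodes)

    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def with_score(self, score: float) -> "Module":
        return replace(self, score=score)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard similarity of two node collections."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
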