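"""Readers and writers for the standard text formats used by the pipeline.

Expression: TSV, genes x samples.  Interactions: two-column TSV or a
BioGRID-TAB-like TSV with configurable symbol columns.  Orthology:
two-column TSV gene <TAB> orthogroup.  Gene sets: GMT.  Modules: TSV and
JSON (JSON round-trips losslessly).  Graph export: GraphML and SIF.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .data import (
    ExpressionTable,
    GeneSetCollection,
    Module,
    OrthologyMap,
    InteractionSet,
)
from .network import OrthogroupNetwork

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_interactions",
    "write_interactions",
    "read_orthology",
    "write_orthology",
    "read_gene_sets",
    "write_gene_sets",
    "read_modules",
    "write_modules",
    "write_modules_tsv",
    "read_network",
    "write_network",
    "export_graphml",
    "export_sif",
]


# ---------------------------------------------------------------- expression
def read_expression_table(path: PathLike, species: str, condition: str) -> ExpressionTable:
    """Parse a genes x samples TSV (header = sample names, col 0 = gene ids).

    Raises ``ValueError`` naming the offending gene on duplicate rows and
    the row/column location on non-numeric cells.  Missing cells (empty or
    ``NA``) are parsed as NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"expression file is empty: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"expression file has no data rows/columns: {path}")
    df.index = df.index.map(str)
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        raw = df[col]
        bad = converted.isna() & raw.notna() & (raw.str.strip() != "") & (
            raw.str.upper() != "NA"
        )
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, column {col!r} "
                f"in {path}"
            )
        values[col] = converted
    return ExpressionTable(species=species, condition=condition, values=values)


def write_expression_table(table: ExpressionTable, path: PathLike) -> None:
    table.values.to_csv(Path(path), sep="\t", index_label="gene", na_rep="NA")


# -------------------------------------------------------------- interactions
def read_interactions(
    path: PathLike,
    species: str,
    dialect: str = "two-column",
    *,
    symbol_columns: tuple[int, int] = (7, 8),
    allow_self_loops: bool = False,
) -> InteractionSet:
    """Read an interaction edge list, collapsing duplicate unordered pairs.

    ``dialect="two-column"`` expects one pair of gene symbols per line
    (extra columns ignored).  ``dialect="biogrid-tab-like"`` takes the
    symbols from ``symbol_columns`` (0-based; the defaults point at the
    official-symbol columns of the classic BioGRID tab format) and skips
    ``#``-prefixed header lines.

    Each line counts as one line of evidence; repeated lines for the same
    unordered pair accumulate.  Self-pairs are dropped (logged) unless
    ``allow_self_loops``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interaction file not found: {path}")
    if dialect not in ("two-column", "biogrid-tab-like"):
        raise ValueError(f"unknown interaction dialect {dialect!r}")
    cols = (0, 1) if dialect == "two-column" else symbol_columns
    iset = InteractionSet(species=species)
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "two-column" and len(fields) == 1:
                fields = line.split()
            if max(cols) >= len(fields):
                raise ValueError(
                    f"malformed interaction line {lineno} in {path}: "
                    f"expected at least {max(cols) + 1} columns"
                )
            a, b = fields[cols[0]].strip(), fields[cols[1]].strip()
            if not a or not b:
                raise ValueError(
                    f"malformed interaction line {lineno} in {path}: empty symbol"
                )
            if a == b and not allow_self_loops:
                n_self += 1
                continue
            iset.add(a, b)
    if n_self:
        log.info("dropped %d self-pair lines from %s", n_self, path)
    if len(iset) == 0:
        log.warning("interaction file %s yielded no edges", path)
    return iset


def write_interactions(iset: InteractionSet, path: PathLike) -> None:
    """Write as a two-column list, repeating each pair per evidence line."""
    with Path(path).open("w") as fh:
        for a, b, count in sorted(iset):
            for _ in range(int(count)):
                fh.write(f"{a}\t{b}\n")


# ----------------------------------------------------------------- orthology
def read_orthology(path: PathLike, casefold: bool = True) -> OrthologyMap:
    """Read a two-column TSV mapping gene identifier -> orthogroup id."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed orthology line {lineno} in {path}")
            mapping[fields[0].strip()] = fields[1].strip()
    return OrthologyMap(mapping, casefold=casefold)


def write_orthology(orthology: OrthologyMap, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        for gene, grp in sorted(orthology.items()):
            fh.write(f"{gene}\t{grp}\n")


# ----------------------------------------------------------------- gene sets
def read_gene_sets(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno} in {path}")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.names()):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# ------------------------------------------------------------------- modules
def _call_to_dict(call) -> Optional[dict]:
    if call is None:
        return None
    if hasattr(call, "to_dict"):
        return call.to_dict()
    return dict(call)


def write_modules(modules: Sequence[Module], path: PathLike) -> None:
    """Serialize modules to JSON (lossless round-trip with read_modules)."""
    payload = []
    for m in modules:
        payload.append(
            {
                "id": m.id,
                "nodes": list(m.nodes),
                "score": m.score,
                "seed": m.seed,
                "time_point": m.time_point,
                "conservation": _call_to_dict(m.conservation),
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_modules(path: PathLike) -> list[Module]:
    from .conservation import ConservationCall  # deferred: avoids cycle

    payload = json.loads(Path(path).read_text())
    modules = []
    for entry in payload:
        call = entry.get("conservation")
        modules.append(
            Module(
                id=entry["id"],
                nodes=tuple(entry["nodes"]),
                score=entry.get("score"),
                seed=entry.get("seed"),
                time_point=entry.get("time_point"),
                conservation=None if call is None else ConservationCall.from_dict(call),
            )
        )
    return modules


def write_modules_tsv(modules: Sequence[Module], path: PathLike) -> None:
    """Flat per-module table for spreadsheet use (not meant to round-trip)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["module_id", "n_nodes", "score", "seed", "time_point", "category", "nodes"]
        )
        for m in modules:
            cat = getattr(m.conservation, "category", "") if m.conservation else ""
            writer.writerow(
                [
                    m.id,
                    m.size,
                    "" if m.score is None else f"{m.score:.6g}",
                    m.seed or "",
                    m.time_point or "",
                    cat,
                    ",".join(m.nodes),
                ]
            )


# ------------------------------------------------------------------- network
def write_network(network: OrthogroupNetwork, path: PathLike) -> None:
    """JSON serialization of the joint network (scores + weighted edges)."""
    payload = {
        "species": list(network.species),
        "nodes": {
            n: {"scores": d["scores"], "z": d["z"], "sign": d["sign"]}
            for n, d in network.graph.nodes(data=True)
        },
        "edges": [
            [u, v, d["weight"]] for u, v, d in network.graph.edges(data=True)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_network(path: PathLike) -> OrthogroupNetwork:
    payload = json.loads(Path(path).read_text())
    g = nx.Graph()
    for node, attrs in payload["nodes"].items():
        g.add_node(
            node,
            scores={k: float(v) for k, v in attrs["scores"].items()},
            z=float(attrs["z"]),
            sign=int(attrs["sign"]),
        )
    for u, v, w in payload["edges"]:
        g.add_edge(u, v, weight=float(w))
    return OrthogroupNetwork(g, tuple(payload["species"]))


def export_graphml(
    network: OrthogroupNetwork,
    modules: Sequence[Module],
    path: PathLike,
    *,
    modules_only: bool = False,
) -> None:
    """GraphML export with per-species scores and module membership.

    ``modules_only`` restricts the export to nodes belonging to a module.
    """
    membership: dict[str, list[str]] = {}
    for m in modules:
        for n in m.nodes:
            membership.setdefault(n, []).append(m.id)
    g = nx.Graph()
    keep = set(membership) if modules_only else set(network.graph.nodes)
    for n in sorted(keep):
        d = network.graph.nodes[n]
        attrs = {"z": float(d["z"]), "sign": int(d["sign"])}
        for sp, val in d["scores"].items():
            attrs[f"score_{sp}"] = float(val)
        attrs["modules"] = ",".join(membership.get(n, []))
        g.add_node(n, **attrs)
    for u, v, d in network.graph.edges(data=True):
        if u in keep and v in keep:
            g.add_edge(u, v, weight=float(d["weight"]))
    nx.write_graphml(g, str(path))


def export_sif(network: OrthogroupNetwork, path: PathLike, relation: str = "pp") -> None:
    """Simple-interaction-format export (``node relation node`` per edge)."""
    with Path(path).open("w") as fh:
        for u, v in sorted(map(sorted, network.graph.edges)):
            fh.write(f"{u}\t{relation}\t{v}\n")
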