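"""Graph and node-set data model: file I/O, harmonization, component utilities.

The interactome is held as an undirected simple :class:`networkx.Graph` with a
positive finite ``weight`` attribute on every edge (1.0 when the source file
carries no weights).  Node ids are opaque, case-sensitive strings; identifier
mapping/curation is out of scope.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "NodeSet",
    "HarmonizationReport",
    "load_network",
    "write_network",
    "load_node_sets",
    "write_node_sets",
    "harmonize",
    "largest_connected_component",
    "induced_subgraph",
]


class Interactome:
    """An undirected, simple, positively weighted graph.

    Parameters
    ----------
    graph:
        Any :class:`networkx.Graph`; self-loops are dropped (with a logged
        warning count), parallel edges cannot occur in ``nx.Graph``, and
        missing ``weight`` attributes default to 1.0.
    name:
        Free-form label carried through derived subgraphs.
    """

    def __init__(self, graph: nx.Graph, name: str = "interactome"):
        if graph.is_directed():
            raise ValidationError("interactome must be undirected")
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in graph.nodes())
        loops = 0
        for u, v, data in graph.edges(data=True):
            u, v = str(u), str(v)
            if u == v:
                loops += 1
                continue
            w = float(data.get("weight", 1.0))
            if not math.isfinite(w) or w <= 0:
                raise ValidationError(
                    f"edge ({u}, {v}) has non-positive or non-finite weight {w!r}"
                )
            g.add_edge(u, v, weight=w)
        if loops:
            logger.warning("dropped %d self-loop(s) from %r", loops, name)
        self._graph = g
        self.name = name
        self.dropped_self_loops = loops

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._graph.nodes())

    def number_of_nodes(self) -> int:
        return self._graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return float(self._graph[u][v]["weight"])

    def degree(self, n: str) -> int:
        return int(self._graph.degree(n))

    def strength(self, n: str) -> float:
        """Sum of incident edge weights (equals degree when unweighted)."""
        return float(self._graph.degree(n, weight="weight"))

    def is_weighted(self) -> bool:
        return any(d["weight"] != 1.0 for _, _, d in self._graph.edges(data=True))

    def sorted_nodes(self) -> list[str]:
        return sorted(self._graph.nodes())

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Interactome({self.name!r}, n={self.number_of_nodes()}, "
            f"m={self.number_of_edges()})"
        )


@dataclass(frozen=True)
class NodeSet:
    """A named set of node ids (disease genes, drug targets, ...)."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"node set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class HarmonizationReport:
    set_name: str
    kept: int
    dropped: tuple[str, ...]


def _try_float(token: str) -> float | None:
    try:
        return float(token)
    except ValueError:
        return None


def _split(line: str) -> list[str]:
    # TSV canonical; tolerate whitespace-delimited dumps when no tab present.
    return line.split("\t") if "\t" in line else line.split()


def _detect_header(lines: list[tuple[int, str]]) -> bool:
    """First line is a header iff its third field is not a number and its
    tokens never recur as node ids in the remaining lines."""
    if not lines:
        return False
    first = _split(lines[0][1])
    if len(first) >= 3 and _try_float(first[2]) is None:
        return True
    if len(lines) > 1:
        later_ids = set()
        for _, line in lines[1:]:
            later_ids.update(_split(line)[:2])
        if first and not (set(first[:2]) & later_ids):
            return len(first) >= 2 and _try_float(first[0]) is None
    return False


def load_network(
    path: str | Path,
    format: str = "edge_list",
    weighted: bool = True,
    name: str | None = None,
) -> Interactome:
    """Load an interactome from an edge-list TSV or a GraphML file.

    Edge-list dialect: ``source<TAB>target[<TAB>weight]`` with an
    auto-detected optional header.  Parallel edges collapse to the maximum
    weight; self-loops are dropped with a logged warning.  ``weighted=False``
    forces every weight to 1.0 regardless of any weight column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in raw.nodes())
        for u, v, data in raw.edges(data=True):
            w = float(data.get("weight", 1.0)) if weighted else 1.0
            _add_max(g, str(u), str(v), w)
        return Interactome(g, name=name or path.stem)
    if format != "edge_list":
        raise ValidationError(f"unknown network format {format!r}")

    lines = [
        (i, line)
        for i, line in enumerate(path.read_text().splitlines(), start=1)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    body = lines[1:] if _detect_header(lines) else lines
    g = nx.Graph()
    for lineno, line in body:
        fields = _split(line)
        if len(fields) == 1 and fields[0]:
            g.add_node(fields[0])  # isolated-node declaration
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}")
        u, v = fields[0], fields[1]
        w = 1.0
        if weighted and len(fields) >= 3:
            parsed = _try_float(fields[2])
            if parsed is None:
                raise ParseError(f"{path}:{lineno}: weight {fields[2]!r} is not a number")
            w = parsed
        if not math.isfinite(w) or w <= 0:
            raise ValidationError(f"{path}:{lineno}: non-positive weight {w}")
        _add_max(g, u, v, w)
    return Interactome(g, name=name or path.stem)


def _add_max(g: nx.Graph, u: str, v: str, w: float) -> None:
    if g.has_edge(u, v):
        g[u][v]["weight"] = max(g[u][v]["weight"], w)
    else:
        g.add_edge(u, v, weight=w)


def write_network(g: Interactome, path: str | Path) -> None:
    """Write a sorted edge-list TSV (round-trips through :func:`load_network`).

    Isolated nodes are written as single-field lines, which the loader reads
    back as node declarations.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.graph.edges()):
            fh.write(f"{u}\t{v}\t{g.weight(u, v)!r}\n")
        for n in sorted(nx.isolates(g.graph)):
            fh.write(f"{n}\n")


def load_node_sets(path: str | Path) -> dict[str, NodeSet]:
    """Load ``{name: [id, ...]}`` JSON into named, de-duplicated node sets."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a JSON object of name -> list of ids")
    out: dict[str, NodeSet] = {}
    for key, ids in data.items():
        if not isinstance(ids, list) or not all(isinstance(i, str) for i in ids):
            raise ValidationError(f"{path}: value for {key!r} must be a list of strings")
        if not ids:
            raise ValidationError(f"{path}: node set {key!r} is empty")
        out[key] = NodeSet(name=key, members=frozenset(ids))
    return out


def write_node_sets(sets: Mapping[str, NodeSet] | Mapping[str, Iterable[str]], path: str | Path) -> None:
    payload = {
        name: sorted(s.members if isinstance(s, NodeSet) else s)
        for name, s in sets.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def harmonize(s: NodeSet, g: Interactome) -> tuple[NodeSet, HarmonizationReport]:
    """Restrict a node set to ids present in the network.

    Returns the filtered set and a report listing dropped ids.  Raises when
    every member is absent (nothing left to analyze).  Idempotent.
    """
    kept = s.members & g.nodes
    dropped = tuple(sorted(s.members - g.nodes))
    if not kept:
        raise ValidationError(
            f"node set {s.name!r}: all {len(s)} member(s) absent from network {g.name!r}"
        )
    if dropped:
        logger.warning(
            "node set %r: dropped %d id(s) absent from the network", s.name, len(dropped)
        )
    report = HarmonizationReport(set_name=s.name, kept=len(kept), dropped=dropped)
    return NodeSet(name=s.name, members=kept), report


def largest_connected_component(g: Interactome) -> Interactome:
    """Induced subgraph on the largest component; ties broken by the
    lexicographically smallest member id."""
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot take the LCC of an empty graph")
    comps = list(nx.connected_components(g.graph))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    return Interactome(g.graph.subgraph(best).copy(), name=g.name)


def induced_subgraph(g: Interactome, s: NodeSet) -> Interactome:
    """Subgraph on ``s.members`` with every edge of ``g`` internal to it."""
    missing = s.members - g.nodes
    if missing:
        raise ValidationError(
            f"node set {s.name!r} not harmonized: {len(missing)} id(s) not in network"
        )
    return Interactome(g.graph.subgraph(s.members).copy(), name=f"{g.name}|{s.name}")
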