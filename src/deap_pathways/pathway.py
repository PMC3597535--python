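"""Pathway graph data model and the tabular edge-list format.

A biological pathway is modelled as a directed graph whose nodes are sets of
protein identifiers (a node may stand for a complex or for a group of
interchangeable gene products) and whose edges carry a regulatory type:
*catalysis* (the reactant promotes the product, multiplier +1) or *inhibition*
(the reactant represses the product, multiplier -1).

The canonical on-disk representation is a tab-separated edge list with header
columns ``pathway_id, edge_id, reactants, products, interaction`` where member
sets are semicolon-joined protein identifiers and ``interaction`` is
``activation``/``catalysis`` or ``inhibition``.  Node identity is the sorted,
semicolon-joined member list, so rows that mention the same protein set share
one node.  Bidirectional relationships are encoded as two opposed directed
edges.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeKind",
    "PathwayNode",
    "PathwayEdge",
    "PathwayGraph",
    "Path",
    "PathwayParseError",
    "parse_pathway_table",
    "write_pathway_table",
    "read_gmt",
    "enumerate_paths",
    "canonical_node_id",
]

REQUIRED_COLUMNS = ("pathway_id", "edge_id", "reactants", "products", "interaction")


class PathwayParseError(ValueError):
    """Raised for malformed pathway tables; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EdgeKind(enum.Enum):
    """Regulatory relationship carried by an edge."""

    CATALYSIS = "catalysis"
    INHIBITION = "inhibition"

    @property
    def multiplier(self) -> int:
        """Signed multiplier: +1 for catalysis, -1 for inhibition."""
        return 1 if self is EdgeKind.CATALYSIS else -1


_INTERACTION_ALIASES = {
    "activation": EdgeKind.CATALYSIS,
    "catalysis": EdgeKind.CATALYSIS,
    "inhibition": EdgeKind.INHIBITION,
}


def canonical_node_id(members: Iterable[str]) -> str:
    """Canonical node identity: the sorted, semicolon-joined member list."""
    return ";".join(sorted(members))


@dataclass(frozen=True)
class PathwayNode:
    """A node: a non-empty set of protein identifiers acting together."""

    node_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"node {self.node_id!r} has an empty member set")


@dataclass(frozen=True)
class PathwayEdge:
    """A typed, directed edge between two nodes."""

    edge_id: str
    reactant: str
    product: str
    kind: EdgeKind

    @property
    def T(self) -> int:
        """Edge multiplier: +1 (catalysis) or -1 (inhibition)."""
        return self.kind.multiplier

    @property
    def arrow(self) -> str:
        return "->" if self.kind is EdgeKind.CATALYSIS else "-|"


class PathwayGraph:
    """A directed pathway graph with an outgoing-edge adjacency index.

    Self-loops are permitted (they are explicit single-edge cycles) and
    parallel edges of *differing* kind between the same node pair are kept;
    parallel edges of identical (reactant, product, kind) should be collapsed
    by the caller (the table parser does this).
    """

    def __init__(self, pathway_id: str, nodes: Iterable[PathwayNode],
                 edges: Iterable[PathwayEdge]):
        self.pathway_id = pathway_id
        self.nodes: dict[str, PathwayNode] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise ValueError(
                    f"duplicate node_id {node.node_id!r} in pathway {pathway_id!r}")
            self.nodes[node.node_id] = node
        self.edges: dict[str, PathwayEdge] = {}
        for edge in edges:
            if edge.edge_id in self.edges:
                raise ValueError(
                    f"duplicate edge_id {edge.edge_id!r} in pathway {pathway_id!r}")
            for endpoint in (edge.reactant, edge.product):
                if endpoint not in self.nodes:
                    raise ValueError(
                        f"edge {edge.edge_id!r} references unknown node {endpoint!r}")
            self.edges[edge.edge_id] = edge
        # Outgoing adjacency: node_id -> edges whose reactant is that node,
        # sorted by edge_id for deterministic traversal.
        out: dict[str, list[PathwayEdge]] = {nid: [] for nid in self.nodes}
        for edge in self.edges.values():
            out[edge.reactant].append(edge)
        self._out = {nid: tuple(sorted(es, key=lambda e: e.edge_id))
                     for nid, es in out.items()}
        self._has_incoming = {e.product for e in self.edges.values()}
        self._member_lists = {nid: tuple(sorted(n.members))
                              for nid, n in self.nodes.items()}
        self._acyclic: bool | None = None

    # -- structure queries ------------------------------------------------

    def children_of(self, node_id: str) -> tuple[PathwayEdge, ...]:
        """Edges whose reactant node is ``node_id`` (sorted by edge_id)."""
        return self._out[node_id]

    def leaf_edges(self) -> list[PathwayEdge]:
        """Edges whose reactant node has no incoming edge (recursion seeds)."""
        return sorted((e for e in self.edges.values()
                       if e.reactant not in self._has_incoming),
                      key=lambda e: e.edge_id)

    def member_proteins(self) -> set[str]:
        """Union of all node member sets."""
        return set().union(*(n.members for n in self.nodes.values())) \
            if self.nodes else set()

    def sorted_edges(self) -> list[PathwayEdge]:
        return sorted(self.edges.values(), key=lambda e: e.edge_id)

    def to_networkx(self) -> nx.MultiDiGraph:
        """A networkx view of the graph (edge key = edge_id, attr kind)."""
        g = nx.MultiDiGraph(pathway_id=self.pathway_id)
        for node in self.nodes.values():
            g.add_node(node.node_id, members=set(node.members))
        for edge in self.edges.values():
            g.add_edge(edge.reactant, edge.product, key=edge.edge_id,
                       kind=edge.kind)
        return g

    def is_acyclic(self) -> bool:
        if self._acyclic is None:
            g = self.to_networkx()
            self._acyclic = bool(nx.is_directed_acyclic_graph(g)
                                 and nx.number_of_selfloops(g) == 0)
        return self._acyclic

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"PathwayGraph({self.pathway_id!r}, "
                f"{len(self.nodes)} nodes, {len(self.edges)} edges)")


@dataclass(frozen=True)
class Path:
    """A simple path (or simple cycle) through a pathway.

    The node chain is ``n0, n1, ..., nL`` where ``n0`` is the first edge's
    reactant and ``nk`` the k-th edge's product.  No node repeats, except that
    the final node may equal ``n0``, closing a simple cycle.  The cumulative
    sign of node k is the product of the multipliers of edges 1..k (the sign
    of ``n0`` is +1).
    """

    edges: tuple[PathwayEdge, ...]
    nodes: tuple[str, ...] = field(init=False)
    signs: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("a path must contain at least one edge")
        chain = [self.edges[0].reactant]
        signs = [1]
        for edge in self.edges:
            if edge.reactant != chain[-1]:
                raise ValueError("edges do not chain: "
                                 f"{edge.edge_id} starts at {edge.reactant}, "
                                 f"expected {chain[-1]}")
            chain.append(edge.product)
            signs.append(signs[-1] * edge.T)
        interior = chain[:-1]
        if len(set(interior)) != len(interior) or \
                (chain[-1] in interior and chain[-1] != chain[0]):
            raise ValueError("path repeats a node without closing a cycle")
        object.__setattr__(self, "nodes", tuple(chain))
        object.__setattr__(self, "signs", tuple(signs))

    @property
    def is_cycle(self) -> bool:
        return self.nodes[-1] == self.nodes[0]

    @property
    def edge_ids(self) -> tuple[str, ...]:
        return tuple(e.edge_id for e in self.edges)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def format(self) -> str:
        """Render as ``A->B-|C`` (``->`` catalysis, ``-|`` inhibition)."""
        out = [self.nodes[0]]
        for edge in self.edges:
            out.append(edge.arrow)
            out.append(edge.product)
        return "".join(out)

    def __len__(self) -> int:
        return len(self.edges)


# -- tabular I/O ----------------------------------------------------------


def _split_members(text: str, what: str, line: int) -> frozenset[str]:
    members = frozenset(m.strip() for m in text.split(";") if m.strip())
    if not members:
        raise PathwayParseError(f"empty {what} member list", line)
    return members


def parse_pathway_table(stream: IO[str] | str) -> list[PathwayGraph]:
    """Parse the tab-separated pathway edge-list format.

    Returns one :class:`PathwayGraph` per distinct ``pathway_id``, in order of
    first appearance.  Rows whose (reactant, product, kind) repeat within a
    pathway are collapsed onto the first occurrence; parallel edges of
    differing kind are kept.  Errors report the 1-based line number.
    """
    if isinstance(stream, str):
        with open(stream, encoding="utf-8") as handle:
            return parse_pathway_table(handle)

    header: list[str] | None = None
    col: dict[str, int] = {}
    # pathway_id -> (nodes, edges, seen (reactant, product, kind) keys)
    builders: dict[str, tuple[dict[str, PathwayNode], list[PathwayEdge], set]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in REQUIRED_COLUMNS if c not in header]
            if missing:
                raise PathwayParseError(
                    f"missing required column(s): {', '.join(missing)}", lineno)
            col = {name: header.index(name) for name in REQUIRED_COLUMNS}
            continue
        if len(fields) < len(header):
            raise PathwayParseError(
                f"expected {len(header)} tab-separated fields, got {len(fields)}",
                lineno)
        pathway_id = fields[col["pathway_id"]].strip()
        edge_id = fields[col["edge_id"]].strip()
        interaction = fields[col["interaction"]].strip().lower()
        if interaction not in _INTERACTION_ALIASES:
            raise PathwayParseError(
                f"unknown interaction keyword {interaction!r} "
                f"(expected one of {sorted(_INTERACTION_ALIASES)})", lineno)
        kind = _INTERACTION_ALIASES[interaction]
        reactants = _split_members(fields[col["reactants"]], "reactant", lineno)
        products = _split_members(fields[col["products"]], "product", lineno)
        nodes, edges, seen = builders.setdefault(pathway_id, ({}, [], set()))
        r_id, p_id = canonical_node_id(reactants), canonical_node_id(products)
        nodes.setdefault(r_id, PathwayNode(r_id, reactants))
        nodes.setdefault(p_id, PathwayNode(p_id, products))
        key = (r_id, p_id, kind)
        if key in seen:
            logger.debug("collapsing duplicate edge %s in pathway %s",
                         edge_id, pathway_id)
            continue
        seen.add(key)
        edges.append(PathwayEdge(edge_id, r_id, p_id, kind))
    if header is None:
        raise PathwayParseError("empty pathway table (no header)")
    return [PathwayGraph(pid, nodes.values(), edges)
            for pid, (nodes, edges, _) in builders.items()]


def write_pathway_table(graphs: Iterable[PathwayGraph], stream: IO[str]) -> None:
    """Write graphs in the canonical tab-separated edge-list format."""
    stream.write("\t".join(REQUIRED_COLUMNS) + "\n")
    for graph in graphs:
        for edge in graph.sorted_edges():
            reactants = ";".join(sorted(graph.nodes[edge.reactant].members))
            products = ";".join(sorted(graph.nodes[edge.product].members))
            interaction = ("activation" if edge.kind is EdgeKind.CATALYSIS
                           else "inhibition")
            stream.write("\t".join((graph.pathway_id, edge.edge_id,
                                    reactants, products, interaction)) + "\n")


def read_gmt(stream: IO[str] | str) -> list[PathwayGraph]:
    """Read a GMT gene-set file as edge-less single-node pathways.

    Each line is ``name<TAB>description<TAB>member1<TAB>member2...``.  The
    result is suitable for the set-based statistic only (the graphs carry no
    edges, so the path score is zero by construction).
    """
    if isinstance(stream, str):
        with open(stream, encoding="utf-8") as handle:
            return read_gmt(handle)
    graphs = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise PathwayParseError(
                "GMT line needs name, description and at least one member",
                lineno)
        name, members = fields[0], frozenset(f for f in fields[2:] if f)
        if not members:
            raise PathwayParseError("empty member list", lineno)
        node = PathwayNode(canonical_node_id(members), members)
        graphs.append(PathwayGraph(name, [node], []))
    return graphs


# -- path enumeration (the brute-force oracle substrate) ------------------


def enumerate_paths(graph: PathwayGraph, max_edges: int) -> list[Path]:
    """All simple paths and simple cycles with at most ``max_edges`` edges.

    Every path appears exactly once, in lexicographic order of its edge_id
    sequence.  Rotations of a cycle are distinct paths (they start at
    different nodes).  An empty graph yields an empty list.
    """
    if max_edges < 1:
        raise ValueError("max_edges must be >= 1")
    results: list[Path] = []

    def extend(edges: list[PathwayEdge], visited: set[str], start: str) -> None:
        results.append(Path(tuple(edges)))
        if len(edges) >= max_edges or edges[-1].product == start:
            return  # length bound reached, or cycle already closed
        tip = edges[-1].product
        for child in graph.children_of(tip):
            if child.product in visited and child.product != start:
                continue
            edges.append(child)
            visited.add(child.product)
            extend(edges, visited, start)
            visited.discard(child.product)
            edges.pop()

    for first in graph.sorted_edges():
        extend([first], {first.reactant, first.product}, first.reactant)
    return results
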