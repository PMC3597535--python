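"""Maximal signed-path scoring.

A path ``n0 -> n1 -> ... -> nL`` is scored by the nested signed running sum

    score = E(n0) + T1 * (E(n1) + T2 * (E(n2) + ... + TL * E(nL)))

where ``Tk`` is the multiplier of the k-th edge (+1 catalysis, -1 inhibition)
and ``E(n)`` is the node's differential-expression sum.  Equivalently, node k
contributes ``E(nk)`` weighted by the cumulative product of the upstream edge
multipliers, so a run of coherently regulated nodes (over-expressed
activators, under-expressed targets of inhibition, ...) accumulates a large
magnitude.  The pathway statistic ``s*`` is the maximum absolute path score
over all simple paths and simple cycles, and the reported path is the one
achieving it.

On acyclic graphs the statistic is computed exactly by a per-edge dynamic
programme: for each edge the best (maximum) and worst (minimum) signed score
of any path starting with that edge is memoized, where the continuation past
the edge's product node is either nothing (the path stops there) or the best
or worst continuation through one of the product's outgoing edges.  On cyclic
graphs edges already on the recursion stack are not re-entered and memoized
values depend on the (fixed, sorted) seeding order, so the result is a
deterministic heuristic rather than the exact optimum; the brute-force
enumerator below is the reference on small graphs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

from .expression import ExpressionSummary
from .pathway import Path, PathwayEdge, PathwayGraph, enumerate_paths

__all__ = [
    "ScoreTable",
    "EdgeScore",
    "DeapResult",
    "node_expression",
    "edge_scores",
    "deap_score",
    "deap_statistic",
    "brute_force_score",
]

_STOP = ("STOP", "")


def _summary_mapping(summary) -> Mapping[str, float]:
    if isinstance(summary, ExpressionSummary):
        return summary.values
    return summary


def node_expression(node, summary) -> float:
    """Differential-expression sum of one node's member proteins.

    Members whose E values are exactly equal are collapsed to a single
    contribution: identical values within one node almost always stem from a
    duplicated measurement of the same underlying gene product (redundant
    identifiers, near-identical protein variants), not from two independent
    signals.  Members missing from the summary are skipped (null-effect
    default; the caller tracks coverage).
    """
    values = _summary_mapping(summary)
    seen = set()
    for member in node.members:
        v = values.get(member)
        if v is not None:
            seen.add(float(v))
    return sum(sorted(seen))


def _node_values(graph: PathwayGraph, summary) -> tuple[dict[str, float], int, int]:
    """Per-node E sums plus (measured, total) protein coverage counts."""
    values = _summary_mapping(summary)
    node_e: dict[str, float] = {}
    for nid, node in graph.nodes.items():
        node_e[nid] = node_expression(node, values)
    proteins = graph.member_proteins()
    measured = sum(1 for p in proteins if p in values)
    return node_e, measured, len(proteins)


@dataclass(frozen=True)
class EdgeScore:
    """Memoized extremes of the signed score over paths starting at one edge.

    ``s_max``/``s_min`` are the raw signed extremes; ``max_score``/
    ``min_score`` expose them clamped (``max_score >= 0 >= min_score``), which
    is what downstream consumers combine.  The source pointers name the child
    edge and branch achieving each extreme, or STOP when the extreme path
    ends at this edge's product node.
    """

    s_max: float
    s_min: float
    max_src: tuple[str, str]
    min_src: tuple[str, str]

    @property
    def max_score(self) -> float:
        return max(self.s_max, 0.0)

    @property
    def min_score(self) -> float:
        return min(self.s_min, 0.0)

    @property
    def best(self) -> float:
        """Largest absolute signed score over paths starting at this edge."""
        return max(self.s_max, -self.s_min)


class ScoreTable:
    """Per-edge memo table with backtracking pointers.

    Built lazily; :meth:`compute` fills it by seeding the recursion at leaf
    edges (no upstream edge reaches their reactant set) and then at any
    remaining unvisited edges, in sorted edge_id order, until the edge set is
    exhausted — the latter pass is what reaches closed cycles.
    """

    def __init__(self, graph: PathwayGraph, node_e: Mapping[str, float]):
        self.graph = graph
        self.node_e = dict(node_e)
        self.scores: dict[str, EdgeScore] = {}
        self._stack: set[str] = set()

    def compute(self) -> "ScoreTable":
        limit = max(sys.getrecursionlimit(), 4 * len(self.graph.edges) + 100)
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(limit)
        try:
            for edge in self.graph.leaf_edges():
                self.visit(edge)
            for edge in self.graph.sorted_edges():
                if edge.edge_id not in self.scores:
                    self.visit(edge)
        finally:
            sys.setrecursionlimit(old)
        return self

    def visit(self, edge: PathwayEdge) -> EdgeScore:
        eid = edge.edge_id
        memo = self.scores.get(eid)
        if memo is not None:
            return memo
        self._stack.add(eid)
        product = edge.product
        # Continuation past the product: stop there, or extend through a child.
        c_max = c_min = self.node_e[product]
        max_src = min_src = _STOP
        for child in self.graph.children_of(product):
            if child.edge_id in self._stack:
                continue  # cycle entry: do not re-enter an edge on the stack
            sub = self.visit(child)
            if sub.s_max > c_max:
                c_max, max_src = sub.s_max, (child.edge_id, "max")
            if sub.s_min < c_min:
                c_min, min_src = sub.s_min, (child.edge_id, "min")
        e_r = self.node_e[edge.reactant]
        t = edge.T
        if t >= 0:
            score = EdgeScore(e_r + t * c_max, e_r + t * c_min, max_src, min_src)
        else:
            score = EdgeScore(e_r + t * c_min, e_r + t * c_max, min_src, max_src)
        self._stack.discard(eid)
        self.scores[eid] = score
        return score

    def reconstruct(self, edge_id: str, branch: str) -> Path:
        """Follow argmax/argmin pointers from an edge into a Path."""
        edges = []
        current, which = edge_id, branch
        while True:
            edge = self.graph.edges[current]
            edges.append(edge)
            score = self.scores[current]
            src = score.max_src if which == "max" else score.min_src
            if src == _STOP:
                return Path(tuple(edges))
            current, which = src


@dataclass
class DeapResult:
    """Per-pathway outcome: statistic, best path, and (optional) p/q values."""

    pathway_id: str
    statistic: float
    signed_score: float
    path: Path | None
    p_value: float | None = None
    q_value: float | None = None
    n_proteins: int = 0
    n_measured: int = 0
    flags: tuple[str, ...] = ()

    def path_string(self) -> str:
        return self.path.format() if self.path is not None else ""


def edge_scores(edge: PathwayEdge, graph: PathwayGraph, summary,
                table: ScoreTable | None = None) -> tuple[float, float]:
    """Clamped (max_score, min_score) for one edge, memoizing into ``table``.

    ``max_score`` is the positive part of the best signed path score starting
    at the edge and ``min_score`` the negative part of the worst; both are 0
    when no path starting here reaches past that sign.
    """
    if table is None:
        node_e, _, _ = _node_values(graph, summary)
        table = ScoreTable(graph, node_e)
    score = table.visit(edge)
    return score.max_score, score.min_score


def deap_score(graph: PathwayGraph, summary) -> DeapResult:
    """Score a pathway: statistic ``s*``, signed score, and the best path.

    The statistic is the maximum over all memoized edges of
    ``max(max_score, -min_score)``; ties are broken toward the positive
    branch and then toward the lexicographically smallest starting edge_id,
    making results deterministic under a fixed edge ordering.  A pathway with
    no edges scores 0 with an empty path (flagged).
    """
    node_e, measured, total = _node_values(graph, summary)
    if not graph.edges:
        return DeapResult(graph.pathway_id, 0.0, 0.0, None,
                          n_proteins=total, n_measured=measured,
                          flags=("no-edges",))
    table = ScoreTable(graph, node_e).compute()
    best_edge, best_branch, best_value = None, "max", float("-inf")
    for edge in graph.sorted_edges():
        score = table.scores[edge.edge_id]
        for branch, value in (("max", score.s_max), ("min", -score.s_min)):
            if value > best_value:
                best_edge, best_branch, best_value = edge, branch, value
    assert best_edge is not None
    path = table.reconstruct(best_edge.edge_id, best_branch)
    start = table.scores[best_edge.edge_id]
    signed = start.s_max if best_branch == "max" else start.s_min
    flags = () if graph.is_acyclic() else ("cycle-heuristic",)
    return DeapResult(graph.pathway_id, abs(signed), signed, path,
                      n_proteins=total, n_measured=measured, flags=flags)


def deap_statistic(graph: PathwayGraph, summary) -> float:
    """The statistic alone (no path reconstruction) — the rotation-loop core."""
    node_e, _, _ = _node_values(graph, summary)
    if not graph.edges:
        return 0.0
    table = ScoreTable(graph, node_e).compute()
    return max(max(s.s_max, -s.s_min) for s in table.scores.values())


def path_score(path: Path, node_e: Mapping[str, float]) -> float:
    """Nested signed running sum of one path (folded from the final node)."""
    acc = node_e[path.nodes[-1]]
    for edge in reversed(path.edges):
        acc = node_e[edge.reactant] + edge.T * acc
    return acc


def brute_force_score(graph: PathwayGraph, summary,
                      max_edges: int | None = None,
                      max_paths: int = 1_000_000) -> tuple[float, Path | None]:
    """Exhaustive-enumeration oracle: score every path, take the max |score|.

    Ties on absolute score are broken toward the lexicographically smallest
    edge_id sequence (the enumeration order).  Raises if the enumeration
    exceeds ``max_paths``.
    """
    if not graph.edges:
        return 0.0, None
    if max_edges is None:
        max_edges = len(graph.edges)
    paths = enumerate_paths(graph, max_edges)
    if len(paths) > max_paths:
        raise ValueError(
            f"enumeration produced {len(paths)} paths (> {max_paths})")
    node_e, _, _ = _node_values(graph, summary)
    best_path, best_abs, best_signed = None, float("-inf"), 0.0
    for path in paths:  # enumeration order is lexicographic: first win = tie-break
        signed = path_score(path, node_e)
        if abs(signed) > best_abs:
            best_path, best_abs, best_signed = path, abs(signed), signed
    return best_abs, best_path
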