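import numpy as np
import pytest

from deap_pathways.pathway import (EdgeKind, PathwayEdge, PathwayGraph,
                                   PathwayNode)

KIND = {"+": EdgeKind.CATALYSIS, "-": EdgeKind.INHIBITION}


def build_graph(edges, pathway_id="G"):
    """Build a single-protein-per-node graph from (edge_id, r, p, '+'|'-')."""
    names = sorted({e[1] for e in edges} | {e[2] for e in edges})
    nodes = [PathwayNode(n, frozenset([n])) for n in names]
    return PathwayGraph(pathway_id,
                        nodes,
                        [PathwayEdge(eid, r, p, KIND[k])
                         for eid, r, p, k in edges])


def chain_graph(n_nodes, kinds, prefix="N"):
    """A simple chain N1 -> N2 -> ... with per-edge kinds ('+'/'-')."""
    assert len(kinds) == n_nodes - 1
    edges = [(f"e{i}", f"{prefix}{i}", f"{prefix}{i + 1}", kinds[i - 1])
             for i in range(1, n_nodes)]
    return build_graph(edges)


def random_dag(rng, max_nodes=10, p_edge=0.25):
    """Random DAG over a random topological order; both edge kinds, possible
    anti-parallel kind pairs are avoided by construction (i < j only)."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"N{i}" for i in range(n)]
    edges = []
    eid = 0
    for i in range(n):
        for j in range(i + 1, n):
            for kind in "+-":
                if rng.random() < p_edge:
                    eid += 1
                    edges.append((f"e{eid:03d}", names[i], names[j], kind))
    if not edges:
        edges = [("e001", names[0], names[1], "+")]
    return build_graph(edges)


def random_expression(graph, rng):
    return {p: float(v) for p, v in
            zip(sorted(graph.member_proteins()),
                rng.standard_normal(len(graph.member_proteins())))}


@pytest.fixture
def crossroads_graph():
    """Eight-node branched graph: one coherent 3-node route among decoys."""
    return build_graph([
        ("e1", "A3", "A4", "+"),
        ("e2", "A1", "A4", "-"),
        ("e3", "A4", "A7", "+"),
        ("e4", "A2", "A5", "+"),
        ("e5", "A5", "A7", "+"),
        ("e6", "A3", "A6", "+"),
        ("e7", "A6", "A8", "+"),
        ("e8", "A6", "A7", "+"),
    ])


@pytest.fixture(scope="session")
def registry():
    from deap_pathways.simulation import fixture_registry
    return {f.name: f for f in fixture_registry()}
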