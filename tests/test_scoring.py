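import numpy as np
import pytest

from deap_pathways.pathway import PathwayGraph, PathwayNode
from deap_pathways.scoring import (ScoreTable, brute_force_score, deap_score,
                                   deap_statistic, edge_scores,
                                   node_expression)

from conftest import build_graph, chain_graph, random_dag, random_expression


def make_node(members):
    return PathwayNode(";".join(sorted(members)), frozenset(members))


class TestNodeExpression:
    def test_exactly_equal_values_collapse_once(self):
        node = make_node({"A", "B"})
        assert node_expression(node, {"A": 1.743, "B": 1.743}) == 1.743

    def test_zero_value(self):
        assert node_expression(make_node({"A"}), {"A": 0.0}) == 0.0

    def test_distinct_values_sum(self):
        node = make_node({"A", "B"})
        assert node_expression(node, {"A": 1.0, "B": -0.5}) == 0.5

    def test_missing_member_contributes_nothing(self):
        node = make_node({"A", "B"})
        assert node_expression(node, {"A": 2.0}) == 2.0


class TestEdgeScores:
    def test_chain_values_match_path_oracle(self):
        # Oracle by hand over paths starting at each edge:
        #  e2 (B->C): only path B,C scores -5+1 = -4   -> clamped (0, -4)
        #  e1 (A->B): paths A,B = -3 and A,B,C = -2    -> clamped (0, -3)
        graph = build_graph([("e1", "A", "B", "+"), ("e2", "B", "C", "+")])
        summary = {"A": 2.0, "B": -5.0, "C": 1.0}
        assert edge_scores(graph.edges["e2"], graph, summary) == (0.0, -4.0)
        assert edge_scores(graph.edges["e1"], graph, summary) == (0.0, -3.0)

    def test_terminal_edge_zero_expression(self):
        graph = build_graph([("e1", "X", "Y", "+")])
        assert edge_scores(graph.edges["e1"], graph,
                           {"X": 0.0, "Y": 0.0}) == (0.0, 0.0)

    def test_terminal_inhibition_sign_pattern(self):
        # X over-expressed, Y under-expressed, X -| Y: 1 - (-1) = 2
        graph = build_graph([("e1", "X", "Y", "-")])
        assert edge_scores(graph.edges["e1"], graph,
                           {"X": 1.0, "Y": -1.0}) == (2.0, 0.0)

    def test_clamped_invariant_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            graph = random_dag(rng)
            summary = random_expression(graph, rng)
            for edge in graph.sorted_edges():
                hi, lo = edge_scores(edge, graph, summary)
                assert hi >= 0.0 >= lo


class TestDeapScore:
    def test_alternating_inhibitory_string_scores_five(self):
        graph = chain_graph(5, "----")
        summary = {f"N{i}": v for i, v in
                   zip(range(1, 6), [1.0, -1.0, 1.0, -1.0, 1.0])}
        result = deap_score(graph, summary)
        assert result.signed_score == 5.0
        assert result.statistic == 5.0
        assert result.path.nodes == ("N1", "N2", "N3", "N4", "N5")

    def test_chain_with_detrimental_prefix(self):
        graph = build_graph([("e1", "A", "B", "+"), ("e2", "B", "C", "+")])
        result = deap_score(graph, {"A": 2.0, "B": -5.0, "C": 1.0})
        assert result.statistic == 4.0
        assert result.signed_score == -4.0
        assert result.path.nodes == ("B", "C")

    def test_all_zero_expression_scores_zero(self, crossroads_graph):
        summary = {p: 0.0 for p in crossroads_graph.member_proteins()}
        assert deap_score(crossroads_graph, summary).statistic == 0.0

    def test_crossroads_picks_the_coherent_route(self, crossroads_graph):
        summary = {p: 0.0 for p in crossroads_graph.member_proteins()}
        summary.update(A3=1.0, A4=1.0, A7=1.0)
        result = deap_score(crossroads_graph, summary)
        assert result.statistic == 3.0
        assert result.path.nodes == ("A3", "A4", "A7")

    def test_zero_edge_pathway_flagged(self):
        graph = PathwayGraph("empty", [PathwayNode("A", frozenset("A"))], [])
        result = deap_score(graph, {"A": 1.0})
        assert result.statistic == 0.0
        assert result.path is None
        assert "no-edges" in result.flags


class TestBruteForce:
    def test_single_edge_closed_form(self):
        rng = np.random.default_rng(5)
        graph = build_graph([("e1", "A", "B", "+")])
        for _ in range(10):
            a, b = rng.standard_normal(2)
            stat, path = brute_force_score(graph, {"A": a, "B": b})
            assert stat == abs(a + b)
            assert path.nodes == ("A", "B")

    def test_overflow_guard(self):
        rng = np.random.default_rng(6)
        graph = random_dag(rng, max_nodes=8, p_edge=0.9)
        with pytest.raises(ValueError, match="paths"):
            brute_force_score(graph, random_expression(graph, rng),
                              max_paths=2)


class TestOracleEquivalence:
    def test_statistic_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            graph = random_dag(rng)
            summary = random_expression(graph, rng)
            assert deap_statistic(graph, summary) == \
                brute_force_score(graph, summary)[0]

    def test_best_path_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(999)
        for _ in range(100):
            graph = random_dag(rng)
            summary = random_expression(graph, rng)
            result = deap_score(graph, summary)
            _, path = brute_force_score(graph, summary)
            assert result.path.edge_ids == path.edge_ids

    def test_cycle_heuristic_flagged_and_deterministic(self):
        graph = build_graph([("e1", "A", "B", "+"), ("e2", "B", "C", "-"),
                             ("e3", "C", "A", "+")])
        summary = {"A": 1.0, "B": -2.0, "C": 0.5}
        first = deap_score(graph, summary)
        second = deap_score(graph, summary)
        assert "cycle-heuristic" in first.flags
        assert first.statistic == second.statistic
        assert first.path.edge_ids == second.path.edge_ids


class TestScoreProperties:
    def test_sign_symmetry(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            graph = random_dag(rng)
            summary = random_expression(graph, rng)
            flipped = {k: -v for k, v in summary.items()}
            a = deap_score(graph, summary)
            b = deap_score(graph, flipped)
            assert a.statistic == b.statistic
            assert a.signed_score == -b.signed_score

    def test_monotone_extension(self):
        # Appending a child edge whose contribution helps never lowers s*.
        rng = np.random.default_rng(22)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            kinds = "".join(rng.choice(list("+-"), n - 1))
            graph = chain_graph(n, kinds)
            summary = {f"N{i}": float(v) for i, v in
                       zip(range(1, n + 1), rng.standard_normal(n))}
            base = deap_statistic(graph, summary)
            extended = chain_graph(n + 1, kinds + "+")
            for helpful in (1.0, 5.0):
                summary[f"N{n + 1}"] = helpful
                assert deap_statistic(extended, summary) >= base

    def test_determinism_across_runs(self):
        rng = np.random.default_rng(23)
        graph = random_dag(rng)
        summary = random_expression(graph, rng)
        results = [deap_score(graph, summary) for _ in range(3)]
        assert len({r.statistic for r in results}) == 1
        assert len({r.path.edge_ids for r in results}) == 1

    def test_score_table_pointers_reconstruct_valid_paths(self):
        rng = np.random.default_rng(24)
        for _ in range(20):
            graph = random_dag(rng)
            summary = random_expression(graph, rng)
            from deap_pathways.scoring import _node_values
            node_e, _, _ = _node_values(graph, summary)
            table = ScoreTable(graph, node_e).compute()
            for edge in graph.sorted_edges():
                for branch in ("max", "min"):
                    path = table.reconstruct(edge.edge_id, branch)
                    assert path.edges[0] is edge
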