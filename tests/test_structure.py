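"""Clamping, pruning, FFL decoupling, core components and feedback loops."""

import itertools
import random

import pytest

from grnlogic.fixtures import pruning_motif, repressilator
from grnlogic.network import LogicNetwork, generate_kauffman, \
    parse_expressions, parse_truth_tables
from grnlogic.structure import (
    clamp_static,
    core_components,
    decouple_ffl,
    feedback_loops,
    prune_relevant,
)


class TestClampStatic:
    def test_constant_chain_freezes(self):
        net = parse_expressions("A = 1\nB = A\nC = B\n")
        reduced, static = clamp_static(net)
        assert static == {"A": 1, "B": 1, "C": 1}
        assert reduced.names == []

    def test_cycle_of_copies_stays_free(self):
        net = parse_expressions("A = C\nB = A\nC = B\n")
        reduced, static = clamp_static(net)
        assert static == {} and set(reduced.names) == {"A", "B", "C"}

    def test_substitution_shrinks_arity(self):
        net = parse_expressions("A = 0\nB = A or X\n")
        reduced, static = clamp_static(net)
        assert static == {"A": 0}
        assert reduced.regulators["B"] == ["X"]
        assert reduced.functions["B"].table == (0, 1)  # copy of X

    def test_external_inputs_never_clamp(self):
        net = parse_expressions("B = X\n")
        _reduced, static = clamp_static(net)
        assert static == {}


class TestPruneRelevant:
    def test_terminal_and_relay_classification(self):
        """Two terminals fed by one relay; the 2-cycle survives."""
        rep = prune_relevant(pruning_motif())
        assert rep.labels == {"Gene1": "core", "Gene2": "core",
                              "Gene3": "relay", "Gene4": "terminal",
                              "Gene5": "terminal"}
        assert sorted(rep.reduced.names) == ["Gene1", "Gene2"]

    def test_pure_cycle_fully_relevant(self):
        rep = prune_relevant(repressilator())
        assert sorted(rep.reduced.names) == ["A", "B", "C"]
        assert set(rep.labels.values()) == {"core"}

    def test_star_graph_prunes_to_nothing(self):
        net = parse_expressions("L1 = Hub\nL2 = Hub\nL3 = Hub\n")
        rep = prune_relevant(net)
        assert rep.reduced.names == []
        assert rep.labels["L1"] == rep.labels["L2"] == rep.labels["L3"] \
            == "terminal"
        assert rep.labels["Hub"] == "external-input"

    def test_self_loop_hub_stays_relevant(self):
        # a self-regulating hub is a feedback loop of length one and
        # survives pruning even when all its other targets are terminal
        net = parse_expressions("Hub = Hub\nL1 = Hub\nL2 = Hub\n")
        rep = prune_relevant(net)
        assert rep.reduced.names == ["Hub"]

    def test_idempotent(self):
        rep1 = prune_relevant(pruning_motif())
        rep2 = prune_relevant(rep1.reduced)
        assert rep2.reduced.names == rep1.reduced.names
        assert all(lab == "core" for lab in rep2.labels.values())


class TestDecoupleFfl:
    def test_redundant_intermediary(self):
        # f_I = g1, f_S = g1 or I  =>  f'_S = g1
        net = parse_expressions("g1 = g3\ng2 = g1\ng3 = g1 or g2\n")
        reduced = decouple_ffl(net, ["g1"], "g2", "g3")
        assert reduced is not None
        assert reduced.table == (0, 1)

    def test_xor_intermediary_collapses_to_constant(self):
        net = parse_expressions(
            "g1 = g3\ng2 = g1\ng3 = (g1 and not g2) or (g2 and not g1)\n")
        reduced = decouple_ffl(net, ["g1"], "g2", "g3")
        assert set(reduced.table) == {0}

    def test_outside_regulator_fails_precondition(self):
        net = parse_expressions("g2 = g1 and h\ng3 = g1 or g2\n")
        assert decouple_ffl(net, ["g1"], "g2", "g3") is None

    def test_reduced_rule_substitutes_correctly(self):
        net = parse_expressions(
            "i = p1 and p2\ns = p1 or (i and p2)\n")
        reduced = decouple_ffl(net, ["p1", "p2"], "i", "s")
        f_i, f_s = net.functions["i"], net.functions["s"]
        # regulators of s are (p1, i, p2) in appearance order
        for p1, p2 in itertools.product((0, 1), repeat=2):
            assert reduced([p1, p2]) == f_s([p1, f_i([p1, p2]), p2])


class TestCoreComponents:
    def test_decoupled_intermediary_is_peripheral(self):
        net = parse_expressions("g1 = g3\ng2 = g1\ng3 = g1 or g2\n")
        rep = core_components(net)
        assert rep.labels["g2"] == "peripheral"
        assert sorted(rep.reduced.names) == ["g1", "g3"]

    def test_pure_cycle_is_core(self):
        rep = core_components(repressilator())
        assert sorted(rep.reduced.names) == ["A", "B", "C"]

    def test_all_constant_network_empty_core(self):
        net = parse_expressions("A = 1\nB = A\n")
        rep = core_components(net)
        assert rep.reduced.names == []
        assert set(rep.labels.values()) == {"static"}

    def test_two_cycles_are_not_decoupled(self):
        net = parse_expressions("A = B\nB = not A\n")
        rep = core_components(net)
        assert sorted(rep.reduced.names) == ["A", "B"]

    def test_idempotent(self):
        net = parse_expressions(
            "g1 = g3\ng2 = g1\ng3 = g1 or g2\ng4 = g3\n")
        rep1 = core_components(net)
        rep2 = core_components(rep1.reduced)
        assert rep2.reduced.names == rep1.reduced.names
        assert all(lab in ("core", "external-input")
                   for lab in rep2.labels.values())

    def test_labels_partition_nodes(self):
        net = generate_kauffman(12, 2, seed=13)
        rep = core_components(net)
        assert set(rep.labels) == set(net.names)
        assert sum(rep.counts.values()) == net.n


# ---------------------------------------------------------------------------
# Feedback loops
# ---------------------------------------------------------------------------

def dfs_simple_cycles(edges, nodes):
    """Brute-force simple-cycle enumeration (rotation-normalized)."""
    adj = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
    found = set()

    def walk(start, node, path, seen):
        for nxt in adj[node]:
            if nxt == start:
                pivot = path.index(min(path))
                found.add(tuple(path[pivot:] + path[:pivot]))
            elif nxt not in seen and nxt > start:
                walk(start, nxt, path + [nxt], seen | {nxt})

    for start in nodes:
        walk(start, start, [start], {start})
    return found


def _copy_network(edges, nodes):
    """Each node copies (OR of) its in-neighbors; sources become inputs."""
    lines = []
    incoming = {n: [] for n in nodes}
    for u, v in edges:
        incoming[v].append(u)
    for n in nodes:
        if incoming[n]:
            lines.append(f"{n} = " + " or ".join(incoming[n]))
    return parse_expressions("\n".join(lines) + "\n") if lines else \
        LogicNetwork(list(nodes), {}, {n: None for n in nodes})


class TestFeedbackLoops:
    def test_three_cycle_single_loop(self):
        rep = feedback_loops(repressilator())
        assert list(rep.cycles.values()) == [("A", "B", "C")]
        assert rep.length_histogram == {3: 1}

    def test_complete_digraph_on_three_nodes(self):
        nodes = ["A", "B", "C"]
        edges = [(u, v) for u in nodes for v in nodes if u != v]
        net = _copy_network(edges, nodes)
        rep = feedback_loops(net)
        assert len(rep.cycles) == 5
        assert rep.length_histogram == {2: 3, 3: 2}

    def test_self_loop_counts_as_length_one(self):
        net = parse_expressions("A = A\n")
        rep = feedback_loops(net)
        assert rep.length_histogram == {1: 1}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dfs_oracle_on_random_digraphs(self, seed):
        rng = random.Random(seed)
        nodes = [f"n{i}" for i in range(rng.randint(4, 8))]
        edges = [(u, v) for u in nodes for v in nodes
                 if u != v and rng.random() < 0.3]
        net = _copy_network(edges, nodes)
        rep = feedback_loops(net)
        assert set(rep.cycles.values()) == dfs_simple_cycles(edges, nodes)

    def test_edge_support_sums_against_cycle_list(self):
        nodes = ["A", "B", "C"]
        edges = [(u, v) for u in nodes for v in nodes if u != v]
        net = _copy_network(edges, nodes)
        rep = feedback_loops(net, "edgeattr")
        for (u, v), attr in rep.edge_attributes.items():
            in_cycles = sum(
                1 for cyc in rep.cycles.values()
                if any(cyc[i] == u and cyc[(i + 1) % len(cyc)] == v
                       for i in range(len(cyc))))
            assert attr.support == in_cycles

    def test_copy_edge_has_unit_activity_and_positive_sign(self):
        net = parse_expressions("A = B\nB = A\n")
        rep = feedback_loops(net, "edgeattr")
        attr = rep.edge_attributes[("B", "A")]
        assert attr.activity == 1 and attr.sign == "+"

    def test_loopsign_on_repressilator(self):
        rep = feedback_loops(repressilator(), "loopsign")
        assert set(rep.edge_signs[next(iter(rep.cycles))]) == {"-"}

    def test_activity_matches_sensitivity_decomposition(self):
        """Edge activity equals the per-variable term of the sensitivity
        sum (cross-module consistency)."""
        from grnlogic.measures import activity, sensitivity
        net = generate_kauffman(6, 2, seed=3)
        rep = feedback_loops(net, "edgeattr")
        for (u, v), attr in rep.edge_attributes.items():
            pos = net.regulators[v].index(u) + 1
            assert attr.activity == activity(net.functions[v], pos)
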