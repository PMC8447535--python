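import itertools

import networkx as nx
import pytest

from boolfg import (
    BooleanNetwork,
    GeneNode,
    Interaction,
    Sign,
    StateVector,
    activation_rule,
    build_factor_graph,
    control_node_update,
    decode_state,
    inhibition_rule,
    knockout,
    synchronous_step,
    trace_step,
)


@pytest.mark.parametrize(
    "parent,child,expected",
    [(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 1)],
)
def test_activation_truth_table(parent, child, expected):
    assert activation_rule(parent, child) == expected


@pytest.mark.parametrize(
    "parent,child,expected",
    [(0, 0, 0), (0, 1, 1), (1, 0, 0), (1, 1, 0)],
)
def test_inhibition_truth_table(parent, child, expected):
    assert inhibition_rule(parent, child) == expected


def active_majority_oracle(child, votes):
    """Majority over the *active* regulators' truth-table values, tie -> child."""
    table_values = [
        (activation_rule if s is Sign.ACTIVATION else inhibition_rule)(p, child)
        for s, p in votes
        if p == 1
    ]
    ones = sum(table_values)
    zeros = len(table_values) - ones
    if ones > zeros:
        return 1
    if zeros > ones:
        return 0
    return child


class TestControlNodeUpdate:
    @pytest.mark.parametrize("k", range(7))
    def test_exhaustive_against_truth_table_oracle(self, k):
        for signs in itertools.product((Sign.ACTIVATION, Sign.INHIBITION), repeat=k):
            for child in (0, 1):
                for parents in itertools.product((0, 1), repeat=k):
                    votes = list(zip(signs, parents))
                    assert control_node_update(child, votes) == active_majority_oracle(
                        child, votes
                    )

    def test_activator_beats_inactive_inhibitor(self):
        votes = [(Sign.ACTIVATION, 1), (Sign.INHIBITION, 0)]
        assert control_node_update(0, votes) == 1

    def test_all_inactive_parents_keep_state(self):
        votes = [(Sign.ACTIVATION, 0), (Sign.INHIBITION, 0)]
        assert control_node_update(1, votes) == 1
        assert control_node_update(0, votes) == 0

    def test_tie_between_active_parents_keeps_state(self):
        votes = [(Sign.ACTIVATION, 1), (Sign.INHIBITION, 1)]
        assert control_node_update(1, votes) == 1
        assert control_node_update(0, votes) == 0

    def test_no_parents_keep_state(self):
        assert control_node_update(1, []) == 1
        assert control_node_update(0, []) == 0

    def test_strict_mode_counts_inactive_votes(self):
        # one active activator against one inactive inhibitor: the inactive
        # inhibitor's table value equals the child, so strict counting ties
        # on child=0 where the default mode switches on
        votes = [(Sign.ACTIVATION, 1), (Sign.INHIBITION, 0)]
        assert control_node_update(0, votes, strict=True) == 0
        assert control_node_update(0, votes, strict=False) == 1


class TestFactorGraph:
    def test_four_gene_example_is_bipartite(self):
        nodes = tuple(GeneNode(f"x{i}") for i in range(1, 5))
        edges = (
            Interaction("x1", "x2", Sign.ACTIVATION),
            Interaction("x3", "x2", Sign.INHIBITION),
            Interaction("x2", "x3", Sign.ACTIVATION),
            Interaction("x4", "x3", Sign.INHIBITION),
            Interaction("x3", "x4", Sign.ACTIVATION),
        )
        graph = build_factor_graph(BooleanNetwork(nodes, edges))
        assert nx.is_bipartite(graph)
        assert set(graph.neighbors(("f", "x3"))) == {("x", "x2"), ("x", "x3"), ("x", "x4")}

    def test_isolated_node_gets_own_child_edge(self):
        graph = build_factor_graph(BooleanNetwork((GeneNode("a"),)))
        assert graph.degree(("f", "a")) == 1
        assert graph.has_edge(("x", "a"), ("f", "a"))

    def test_yeast_counts(self, yeast):
        graph = build_factor_graph(yeast)
        variables = [n for n in graph if n[0] == "x"]
        controls = [n for n in graph if n[0] == "f"]
        assert (len(variables), len(controls)) == (11, 11)
        assert graph.number_of_edges() == 40
        for name in yeast.names:
            assert graph.degree(("f", name)) == yeast.k(name) + 1

    def test_clamped_gene_has_no_control_node(self, yeast):
        graph = build_factor_graph(knockout(yeast, ["Sic1"]))
        assert ("f", "Sic1") not in graph
        assert ("x", "Sic1") in graph


class TestSynchronousStep:
    def test_start_state_update(self, yeast):
        state = decode_state("10001000100", yeast)
        nxt, _ = synchronous_step(yeast, state)
        assert nxt.to_bitstring() == "01101000100"

    def test_fixed_point_with_inactive_self_degraders(self, yeast):
        state = decode_state("00001000100", yeast)
        nxt, _ = synchronous_step(yeast, state)
        assert nxt == state

    def test_sic1_ko_table_row(self, yeast):
        mutant = knockout(yeast, ["Sic1"])
        state = decode_state("01101000000", mutant)
        nxt, _ = synchronous_step(mutant, state)
        assert nxt.to_bitstring() == "01111001000"

    def test_determinism(self, yeast):
        state = decode_state("10101010101", yeast)
        a = synchronous_step(yeast, state)
        b = synchronous_step(yeast, state)
        assert a == b

    def test_orphan_node_never_changes(self):
        net = BooleanNetwork((GeneNode("a"),))
        for bit in (0, 1):
            nxt, _ = synchronous_step(net, StateVector((bit,)))
            assert nxt.bits == (bit,)

    def test_self_degrading_orphan_decays_after_td(self):
        net = BooleanNetwork((GeneNode("a", self_degrading=True),), t_d=3)
        state, counters = StateVector((1,)), None
        history = []
        for _ in range(4):
            state, counters = synchronous_step(net, state, counters)
            history.append(state.bits[0])
        assert history == [1, 1, 0, 0]

    def test_degradation_waits_full_delay_after_regulators_silence(self):
        net = BooleanNetwork(
            (GeneNode("a", self_degrading=True), GeneNode("b", self_degrading=True)),
            (Interaction("b", "a", Sign.ACTIVATION),),
            t_d=2,
        )
        # while b feeds a, a's counter stays at zero; b (no regulators)
        # decays after two steps, and only two further silent steps later
        # does a follow
        state, counters = StateVector((1, 1)), None
        bits = []
        for _ in range(4):
            state, counters = synchronous_step(net, state, counters)
            bits.append(state.bits)
        assert [b[1] for b in bits] == [1, 0, 0, 0]
        assert [b[0] for b in bits] == [1, 1, 1, 0]

    def test_state_length_mismatch(self, yeast):
        with pytest.raises(ValueError, match="length"):
            synchronous_step(yeast, StateVector((0, 1)))


def test_trace_step_reports_votes(yeast):
    records = trace_step(yeast, decode_state("10001000100", yeast))
    by_gene = {r["gene"]: r for r in records}
    mbf = by_gene["MBF"]
    assert mbf["active_activators"] == 1 and mbf["active_inhibitors"] == 0
    assert mbf["mu"] == 1
    assert by_gene["Cln3"]["mu"] == 0  # self-degrades, no regulators
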