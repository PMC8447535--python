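"""Factor-graph construction and the one-step synchronous network update.

The signed Boolean network is viewed as a bipartite factor graph: one
variable node per gene holds the gene's current state, and one control node
per non-clamped gene evaluates its update function.  A variable node sends
its state unchanged (message ``lambda_ij``) to every adjacent control node,
including its own; the control node evaluates a signed truth table per
regulator and aggregates by majority vote into a belief ``mu_i`` that
becomes the gene's next state.

Truth tables (regulator ``p``, current child state ``c``):

* activation:  ``c' = p OR c``
* inhibition:  ``c' = (p XOR c) AND c``  — i.e. 0 whenever the inhibitor is
  active, otherwise the child keeps its state.

Both rules reduce to the child's current state when the regulator is
inactive, so an inactive regulator carries no information.  The default
majority therefore counts only *active* regulators: active activators vote
1, active inhibitors vote 0, and a tie (including "no active regulators")
keeps the current state.  A ``strict`` mode that counts all regulators'
truth-table values, one vote each, is provided for comparison; it does not
reproduce the yeast cell-cycle trajectories.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx

from .network import BooleanNetwork, Sign, StateVector


def activation_rule(parent: int, child: int) -> int:
    """Activation truth table: the child is on if regulator or child is on."""
    return parent | child


def inhibition_rule(parent: int, child: int) -> int:
    """Inhibition truth table: an active inhibitor forces the child off."""
    return (parent ^ child) & child


def build_factor_graph(net: BooleanNetwork) -> nx.Graph:
    """Bipartite factor graph of ``net`` as an undirected networkx graph.

    Variable nodes are ``("x", name)`` (attribute ``bipartite=0``), control
    nodes ``("f", name)`` (``bipartite=1``).  Every non-clamped gene gets a
    control node joined to its regulators' variable nodes (edge attribute
    ``sign``) and to its own child variable (``sign=None``), so
    ``degree(f_i) = k_i + 1``.  Clamped genes have no control node.
    """
    graph = nx.Graph()
    for node in net.nodes:
        graph.add_node(("x", node.name), bipartite=0, self_degrading=node.self_degrading)
    for node in net.nodes:
        if node.name in net.clamps:
            continue
        control = ("f", node.name)
        graph.add_node(control, bipartite=1)
        for ia in net.regulators(node.name):
            graph.add_edge(("x", ia.source), control, sign=ia.sign)
        graph.add_edge(("x", node.name), control, sign=None)
    return graph


def control_node_update(
    child_state: int,
    parent_votes: Sequence[tuple[Sign, int]],
    strict: bool = False,
) -> int:
    """Next state of a gene from its current state and regulator votes.

    ``parent_votes`` is a sequence of ``(sign, regulator_state)`` pairs.  In
    the default mode, let A (I) be the number of active activators
    (inhibitors): the result is 1 if A > I, 0 if I > A, and the current
    ``child_state`` on a tie or when no regulator is active.  In ``strict``
    mode every regulator casts its truth-table value as a vote and the
    plain majority is taken, ties again keeping the current state.
    """
    if strict:
        ones = 0
        for sign, parent_state in parent_votes:
            rule = activation_rule if sign is Sign.ACTIVATION else inhibition_rule
            ones += rule(parent_state, child_state)
        zeros = len(parent_votes) - ones
        if ones > zeros:
            return 1
        if zeros > ones:
            return 0
        return child_state
    active_activators = sum(
        1 for sign, state in parent_votes if state and sign is Sign.ACTIVATION
    )
    active_inhibitors = sum(
        1 for sign, state in parent_votes if state and sign is Sign.INHIBITION
    )
    if active_activators > active_inhibitors:
        return 1
    if active_inhibitors > active_activators:
        return 0
    return child_state


def initial_counters(net: BooleanNetwork) -> tuple[int, ...]:
    """Zeroed self-degradation counters, one per node."""
    return (0,) * net.n


def synchronous_step(
    net: BooleanNetwork,
    state: StateVector,
    counters: tuple[int, ...] | None = None,
    strict: bool = False,
) -> tuple[StateVector, tuple[int, ...]]:
    """One synchronous update of all genes; returns (next state, counters).

    Order of operations per gene: majority vote, then clamp enforcement,
    then the self-degradation override.  The per-node counters track how
    many consecutive completed steps a self-degrading gene has spent at 1
    with every regulator at 0; when the counter reaches ``t_d`` the gene is
    forced to 0, overriding the vote.  With ``t_d = 1`` the counters are a
    function of the current state, so callers doing plain state-space
    enumeration may ignore them.
    """
    if len(state) != net.n:
        raise ValueError(f"state length {len(state)} does not match network size {net.n}")
    if counters is None:
        counters = initial_counters(net)
    regulator_table = net.regulator_table()
    bits = state.bits
    next_bits: list[int] = []
    next_counters: list[int] = []
    for i, node in enumerate(net.nodes):
        regs = regulator_table[i]
        if node.name in net.clamps:
            next_bits.append(net.clamps[node.name])
            next_counters.append(0)
            continue
        votes = [(sign, bits[src]) for src, sign in regs]
        nxt = control_node_update(bits[i], votes, strict=strict)
        counter = 0
        if node.self_degrading:
            all_regs_silent = all(bits[src] == 0 for src, _ in regs)
            if bits[i] == 1 and all_regs_silent:
                counter = counters[i] + 1
            if counter >= net.t_d:
                nxt = 0
        next_bits.append(nxt)
        next_counters.append(counter)
    return StateVector(tuple(next_bits)), tuple(next_counters)


def trace_step(net: BooleanNetwork, state: StateVector, strict: bool = False) -> list[dict]:
    """Per-gene message trace for one update: lambda inputs, tallies, belief.

    Returns one record per gene with the incoming regulator messages, the
    active-activator/active-inhibitor tallies and the outgoing belief; handy
    for debugging update rules step by step.
    """
    records = []
    next_state, _ = synchronous_step(net, state, strict=strict)
    for i, node in enumerate(net.nodes):
        regs = net.regulators(node.name)
        lambdas = {ia.source: state.bits[net.index[ia.source]] for ia in regs}
        active_a = sum(
            1 for ia in regs if ia.sign is Sign.ACTIVATION and lambdas[ia.source]
        )
        active_i = sum(
            1 for ia in regs if ia.sign is Sign.INHIBITION and lambdas[ia.source]
        )
        records.append(
            {
                "gene": node.name,
                "state": state.bits[i],
                "lambda": dict(lambdas),
                "active_activators": active_a,
                "active_inhibitors": active_i,
                "mu": next_state.bits[i],
            }
        )
    return records
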