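"""Trajectories, attractors, basins, and yeast cell-cycle phase labels.

Attractor search enumerates the full state space (2^n states) and follows
every initial state to absorption with memoized successor lookup, so basins
are exact and partition the state space.  With the default self-degradation
delay ``t_d = 1`` the update is a pure function of the current state and the
whole transition table is built vectorized with numpy; for larger delays the
dynamical state is the pair (state, degradation counters) and a generic
memoized traversal over augmented states is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import initial_counters, synchronous_step
from .network import (
    BooleanNetwork,
    Sign,
    StateVector,
    YEAST_GENE_ORDER,
    decode_state,
)

#: Hard ceiling on exhaustive enumeration (2^cap states).
DEFAULT_ENUMERATION_CAP = 22

PHASES = ("Start", "G1", "S", "G2", "M", "Stationary G1")


class UnsupportedNetworkError(ValueError):
    """Raised when a yeast-specific operation is applied to another network."""


@dataclass(frozen=True)
class Trajectory:
    """A simulated path from an initial state to absorption.

    ``states`` holds every visited state including the absorbing fixed point
    (once) or the full first pass through a cycle.  ``terminal`` is one of
    ``fixed_point``, ``cycle`` or ``max_steps``; ``cycle_states`` is the
    recurring block for cycles.  ``transitions`` counts state updates, i.e.
    ``len(states) - 1``.
    """

    states: tuple[StateVector, ...]
    terminal: str
    cycle_states: tuple[StateVector, ...] = ()
    phases: tuple[str, ...] | None = None

    @property
    def transitions(self) -> int:
        return len(self.states) - 1

    def bitstrings(self) -> tuple[str, ...]:
        return tuple(s.to_bitstring() for s in self.states)


@dataclass(frozen=True)
class Attractor:
    """A fixed point or cycle together with its exact basin size."""

    kind: str  # "singleton" or "cycle"
    states: tuple[str, ...]  # bitstrings; cycles in visit order, canonical start
    basin_size: int

    @property
    def period(self) -> int:
        return len(self.states)


def simulate(
    net: BooleanNetwork,
    init: StateVector | str,
    max_steps: int | None = None,
    strict: bool = False,
) -> Trajectory:
    """Iterate the synchronous update from ``init`` until recurrence.

    Recurrence is detected on the augmented pair (state, degradation
    counters); with ``t_d = 1`` this coincides with plain state recurrence.
    Returns a fixed point when the recurring block has period 1, a cycle
    otherwise, or flags ``max_steps`` exhaustion (which cannot happen at the
    default budget of ``4 * 2**n`` capped at one million steps).
    """
    if isinstance(init, str):
        init = decode_state(init, net)
    if max_steps is None:
        max_steps = min(4 * 2**net.n, 1_000_000)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    counters = initial_counters(net)
    states = [init]
    seen = {(init.bits, counters): 0}
    for _ in range(max_steps):
        nxt, counters = synchronous_step(net, states[-1], counters, strict=strict)
        key = (nxt.bits, counters)
        if key in seen:
            start = seen[key]
            period = len(states) - start
            if period == 1:
                return Trajectory(tuple(states), "fixed_point")
            return Trajectory(tuple(states), "cycle", cycle_states=tuple(states[start:]))
        seen[key] = len(states)
        states.append(nxt)
    return Trajectory(tuple(states), "max_steps")


# -- vectorized transition table (t_d == 1) --------------------------------


def _state_matrix(n: int) -> np.ndarray:
    """All 2^n states as an (2^n, n) bit matrix; bit 0 is the leftmost char."""
    idx = np.arange(2**n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1, dtype=np.int64)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def transition_table(net: BooleanNetwork, strict: bool = False) -> np.ndarray:
    """Successor index for every state; valid when ``t_d == 1``.

    State ``i`` encodes the bitstring of ``i`` in ``n`` binary digits, the
    first gene being the most significant bit (matching the codec).
    """
    n = net.n
    bits = _state_matrix(n)
    nxt = np.empty_like(bits)
    regulator_table = net.regulator_table()
    for i, node in enumerate(net.nodes):
        if node.name in net.clamps:
            nxt[:, i] = net.clamps[node.name]
            continue
        regs = regulator_table[i]
        current = bits[:, i]
        if strict:
            ones = np.zeros(bits.shape[0], dtype=np.int32)
            for src, sign in regs:
                parent = bits[:, src]
                if sign is Sign.ACTIVATION:
                    ones += parent | current
                else:
                    ones += (parent ^ current) & current
            zeros = len(regs) - ones
            col = np.where(ones > zeros, 1, np.where(zeros > ones, 0, current))
        else:
            act = np.zeros(bits.shape[0], dtype=np.int32)
            inh = np.zeros(bits.shape[0], dtype=np.int32)
            for src, sign in regs:
                if sign is Sign.ACTIVATION:
                    act += bits[:, src]
                else:
                    inh += bits[:, src]
            col = np.where(act > inh, 1, np.where(inh > act, 0, current))
        if node.self_degrading:
            if regs:
                silent = np.ones(bits.shape[0], dtype=bool)
                for src, _ in regs:
                    silent &= bits[:, src] == 0
            else:
                silent = np.ones(bits.shape[0], dtype=bool)
            col = np.where((current == 1) & silent, 0, col)
        nxt[:, i] = col.astype(np.int8)
    shifts = np.arange(n - 1, -1, -1, dtype=np.int64)
    return (nxt.astype(np.int64) << shifts[None, :]).sum(axis=1)


def _attractors_from_successors(succ: np.ndarray, n: int) -> list[Attractor]:
    """Attractors of the functional graph ``i -> succ[i]`` with exact basins."""
    size = succ.shape[0]
    attractor_id = np.full(size, -1, dtype=np.int64)
    attractor_states: list[tuple[int, ...]] = []
    for start in range(size):
        if attractor_id[start] >= 0:
            continue
        path: list[int] = []
        position: dict[int, int] = {}
        s = start
        while attractor_id[s] < 0 and s not in position:
            position[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if attractor_id[s] >= 0:
            aid = int(attractor_id[s])
        else:
            cycle = path[position[s]:]
            aid = len(attractor_states)
            attractor_states.append(tuple(cycle))
        for state in path:
            attractor_id[state] = aid
    basins = np.bincount(attractor_id, minlength=len(attractor_states))
    attractors = []
    for aid, cycle in enumerate(attractor_states):
        # canonical rotation: begin at the lexicographically smallest bitstring
        smallest = min(range(len(cycle)), key=lambda i: cycle[i])
        ordered = cycle[smallest:] + cycle[:smallest]
        bitstrings = tuple(format(s, f"0{n}b") for s in ordered)
        kind = "singleton" if len(ordered) == 1 else "cycle"
        attractors.append(Attractor(kind, bitstrings, int(basins[aid])))
    attractors.sort(key=lambda a: (-a.basin_size, a.states))
    return attractors


def find_attractors(
    net: BooleanNetwork,
    cap: int = DEFAULT_ENUMERATION_CAP,
    strict: bool = False,
) -> list[Attractor]:
    """All attractors of ``net`` with exact basin sizes over 2^n states.

    Degradation counters are reset to zero for every initial state.  Basin
    sizes sum to 2^n.  Networks above the enumeration cap are refused:
    sample initial states with :func:`simulate` instead.
    """
    if net.n > cap:
        raise ValueError(
            f"exhaustive enumeration of 2^{net.n} states exceeds the cap of 2^{cap}; "
            "sample initial states with simulate() instead"
        )
    if net.t_d == 1 or not any(node.self_degrading for node in net.nodes):
        succ = transition_table(net, strict=strict)
        return _attractors_from_successors(succ, net.n)
    return _find_attractors_augmented(net, strict=strict)


def _find_attractors_augmented(net: BooleanNetwork, strict: bool = False) -> list[Attractor]:
    """Memoized traversal on (state, counters) pairs, for t_d > 1."""
    n = net.n
    zero = initial_counters(net)
    attractor_of: dict[tuple, int] = {}
    attractor_states: list[tuple[str, ...]] = []
    basins: list[int] = []
    for idx in range(2**n):
        state = decode_state(format(idx, f"0{n}b"), net)
        key = (state.bits, zero)
        path: list[tuple] = []
        position: dict[tuple, int] = {}
        states_on_path: list[StateVector] = []
        counters = zero
        while key not in attractor_of and key not in position:
            position[key] = len(path)
            path.append(key)
            states_on_path.append(state)
            state, counters = synchronous_step(net, state, counters, strict=strict)
            key = (state.bits, counters)
        if key in attractor_of:
            aid = attractor_of[key]
        else:
            cycle = states_on_path[position[key]:]
            bitstrings = tuple(s.to_bitstring() for s in cycle)
            smallest = min(range(len(bitstrings)), key=lambda i: bitstrings[i])
            canonical = bitstrings[smallest:] + bitstrings[:smallest]
            aid = len(attractor_states)
            attractor_states.append(canonical)
            basins.append(0)
        for visited in path:
            if visited not in attractor_of:
                attractor_of[visited] = aid
        basins[aid] += 1  # one initial state per outer iteration
    attractors = [
        Attractor("singleton" if len(states) == 1 else "cycle", states, basins[aid])
        for aid, states in enumerate(attractor_states)
    ]
    attractors.sort(key=lambda a: (-a.basin_size, a.states))
    return attractors


# -- yeast cell-cycle phase labeling ---------------------------------------


def _require_yeast(net: BooleanNetwork) -> None:
    if net.names != YEAST_GENE_ORDER:
        raise UnsupportedNetworkError(
            "phase labeling is specific to the built-in yeast cell-cycle network"
        )


def stationary_pattern(net: BooleanNetwork) -> tuple[int, ...]:
    """Bits of the stationary G1 resting state, honoring any clamps.

    The unperturbed pattern has only the stabilizers Cdh1 and Sic1 active;
    clamped genes take their clamp value instead.
    """
    _require_yeast(net)
    return tuple(
        net.clamps.get(name, 1 if name in ("Cdh1", "Sic1") else 0)
        for name in YEAST_GENE_ORDER
    )


def label_phases(traj: Trajectory, net: BooleanNetwork) -> tuple[str, ...]:
    """Cell-cycle phase label per trajectory step (yeast network only).

    A forward-advancing phase machine: the stationary G1 resting pattern is
    recognized first; otherwise the phase starts at Start while the Cln3
    size signal is on, moves to G1 when it falls, to S on the first step
    with the S-cyclin Clb5,6 active, to G2 once a mitotic marker (Clb1,2,
    Cdc20,14 or Mcm1/SFF) is active, and to M once the G1 transcription
    factors MBF and SBF are off while the mitotic regulators (Clb1,2 or,
    failing that, Cdc20,14) are active.  The G1/S boundary
    matches the published knockout tables exactly; the printed G2/S split
    inside some knockout tables follows no single marker and may differ by
    one step mid-trajectory.
    """
    _require_yeast(net)
    idx = net.index
    stationary = stationary_pattern(net)
    labels: list[str] = []
    phase: str | None = None
    for state in traj.states:
        bits = state.bits
        if bits == stationary:
            phase = "Stationary G1"
            labels.append(phase)
            continue
        if phase is None or phase == "Stationary G1":
            phase = "Start" if bits[idx["Cln3"]] == 1 else "G1"
        elif phase == "Start" and bits[idx["Cln3"]] == 0:
            phase = "G1"
        if phase in ("Start", "G1") and bits[idx["Clb5,6"]] == 1:
            phase = "S"
        if phase == "S" and (
            bits[idx["Clb1,2"]] or bits[idx["Cdc20,14"]] or bits[idx["Mcm1/SFF"]]
        ):
            phase = "G2"
        if phase == "G2" and (
            (bits[idx["Clb1,2"]] or bits[idx["Cdc20,14"]])
            and not bits[idx["MBF"]]
            and not bits[idx["SBF"]]
        ):
            phase = "M"
        labels.append(phase)
    return tuple(labels)


def is_viable(traj: Trajectory, net: BooleanNetwork | None = None) -> bool:
    """Whether a (yeast) trajectory completes a full division cycle.

    Viable means the cell passes through all four phases G1, S, G2 and M
    and comes to rest at the stationary G1 fixed point.
    """
    phases = traj.phases
    if phases is None:
        if net is None:
            raise ValueError("trajectory has no phase labels; pass the network")
        phases = label_phases(traj, net)
    visited = set(phases)
    return (
        {"G1", "S", "G2", "M"} <= visited
        and traj.terminal == "fixed_point"
        and phases[-1] == "Stationary G1"
    )


def labeled_trajectory(
    net: BooleanNetwork,
    init: StateVector | str,
    max_steps: int | None = None,
    strict: bool = False,
) -> Trajectory:
    """Simulate and attach phase labels (yeast network only)."""
    traj = simulate(net, init, max_steps=max_steps, strict=strict)
    phases = label_phases(traj, net)
    return Trajectory(traj.states, traj.terminal, traj.cycle_states, phases)
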