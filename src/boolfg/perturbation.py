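"""Structural and state perturbations: knockouts, over-expression, bit flips.

A gene knockout models deletion of the coding region: the gene's state is
clamped to 0 and its control node is removed from the factor graph, so it
casts no vote on itself but still appears (permanently inactive, hence
abstaining) among its targets' regulators.  Over-expression clamps to 1.
Random state perturbation flips every bit independently with a small
probability epsilon, modeling noise-driven switching of gene expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory, is_viable, labeled_trajectory
from .network import BooleanNetwork, StateVector, decode_state

logger = logging.getLogger(__name__)


def _clamp(net: BooleanNetwork, genes: list[str], value: int) -> BooleanNetwork:
    index = net.index
    for gene in genes:
        if gene not in index:
            raise KeyError(
                f"unknown gene {gene!r}; valid names: {', '.join(net.names)}"
            )
        if gene in net.clamps and net.clamps[gene] != value:
            logger.warning(
                "gene %s already clamped to %d; overriding with %d",
                gene, net.clamps[gene], value,
            )
    return net.with_clamps({gene: value for gene in genes})


def knockout(net: BooleanNetwork, genes: list[str]) -> BooleanNetwork:
    """Copy of ``net`` with the listed genes deleted (clamped to 0)."""
    return _clamp(net, list(genes), 0)


def overexpress(net: BooleanNetwork, gene: str) -> BooleanNetwork:
    """Copy of ``net`` with ``gene`` constitutively expressed (clamped to 1)."""
    return _clamp(net, [gene], 1)


def perturb_state(
    state: StateVector,
    epsilon: float,
    rng: np.random.Generator | int,
) -> StateVector:
    """Flip each bit independently with probability ``epsilon``.

    ``rng`` may be a seeded :class:`numpy.random.Generator` or an integer
    seed; results are reproducible for a given seed.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    flips = rng.random(len(state)) < epsilon
    bits = tuple(int(b ^ f) for b, f in zip(state.bits, flips))
    return StateVector(bits)


def apply_clamps(net: BooleanNetwork, state: StateVector | str) -> StateVector:
    """Force clamped genes of ``net`` to their clamp value in ``state``."""
    if isinstance(state, str):
        state = decode_state(state, net)
    idx = net.index
    bits = list(state.bits)
    for gene, value in net.clamps.items():
        bits[idx[gene]] = value
    return StateVector(tuple(bits))


@dataclass(frozen=True)
class KnockoutReport:
    """Outcome of a knockout simulation: trajectory, labels and verdict."""

    genes: tuple[str, ...]
    trajectory: Trajectory
    terminal_phase: str
    viable: bool
    annotation: str


def knockout_report(
    net: BooleanNetwork,
    genes: list[str],
    init: StateVector | str,
    max_steps: int | None = None,
    strict: bool = False,
) -> KnockoutReport:
    """Delete ``genes``, simulate from ``init`` and classify the outcome.

    The initial state has the deleted genes forced to 0 (knockout tables
    start from the Start excited state with the clamped bits overridden).
    The verdict is ``"viable"`` when the cycle completes all four phases
    and rests at stationary G1; an arrest before the first S phase that
    ends in the resting pattern is reported as a pre-Start arrest,
    otherwise the arrest phase is named.
    """
    mutant = knockout(net, genes)
    start = apply_clamps(mutant, init)
    traj = labeled_trajectory(mutant, start, max_steps=max_steps, strict=strict)
    terminal_phase = traj.phases[-1]
    viable = is_viable(traj, mutant)
    if viable:
        annotation = "viable"
    elif terminal_phase == "Stationary G1" and "S" not in traj.phases:
        annotation = "arrests before the Start transition"
    else:
        annotation = f"arrests in {terminal_phase}"
    return KnockoutReport(tuple(genes), traj, terminal_phase, viable, annotation)
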