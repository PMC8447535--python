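"""Density evolution: error-probability propagation under state perturbations.

Suppose each gene-state message is independently in error with probability
``eps`` (an i.i.d. random flip over the variable nodes).  For a single
signed pairwise comparison at a control node — the truth-table output
computed from one regulator message and the child message — the output is
wrong with probability

    y = eps * (1 - eps / 2),

identically for activation and inhibition: a single flipped message changes
the table output with conditional probability 1/2 over uniform states, and
two flips also err with probability 1/2.  A degree-``j`` control node forms
``j - 1`` such pairwise values and takes the majority, so (treating the
comparisons as independent, the locally tree-like idealization) its output
errs with the binomial tail probability

    sum_{k = ceil((j-1)/2)}^{j-1} C(j-1, k) y^k (1 - y)^(j-1-k),

where an exact tie counts as an error.  Averaging over the edge-perspective
degree distribution rho(x) gives the one-step recursion eps_l = f(eps_{l-1})
whose iteration tracks whether an initial disturbance dies out or persists.

The first-order expansion eps_l ~ rho_1 + (rho_2 + 2*rho_3) * eps_{l-1}
yields the resilience conditions: errors vanish only if rho_1 = 0 and
rho_2 + 2*rho_3 < 1 (hence rho_3 < 0.5) — a network needs most of its
control nodes at degree > 3 to heal random state disturbances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .network import DegreeDistribution


def _check_probability(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def pairwise_error_update(eps: float) -> float:
    """Error probability of one signed pairwise truth-table comparison."""
    _check_probability(eps, "eps")
    return eps * (1.0 - 0.5 * eps)


def degree_error(y: float, j: int) -> float:
    """Majority-vote error at a degree-``j`` control node, ties included.

    ``y`` is the per-comparison error probability.  For ``j = 1`` the
    majority is empty and the value is 1: a gene without regulators cannot
    correct its own error.
    """
    _check_probability(y, "y")
    if j < 1:
        raise ValueError(f"control-node degree must be >= 1, got {j}")
    m = j - 1
    lower = math.ceil(m / 2)
    return math.fsum(
        math.comb(m, k) * y**k * (1.0 - y) ** (m - k) for k in range(lower, m + 1)
    )


def de_step(eps: float, rho: DegreeDistribution) -> float:
    """One round of the density-evolution recursion for distribution ``rho``."""
    y = pairwise_error_update(eps)
    return math.fsum(r * degree_error(y, j) for j, r in rho.coefficients.items())


@dataclass(frozen=True)
class DEResult:
    """The iterated error-probability sequence with convergence diagnostics."""

    epsilons: tuple[float, ...]
    converged: bool
    limit: float
    iterations: int
    tol: float

    @property
    def vanishes(self) -> bool:
        """Whether the disturbance has effectively died out."""
        return self.converged and self.limit < max(self.tol, 1e-9)


def de_evolve(
    eps0: float = 0.25,
    rho: DegreeDistribution | None = None,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> DEResult:
    """Iterate the recursion from ``eps0`` until successive change < ``tol``.

    The full sequence is reported so non-monotone behavior stays visible;
    the last value is the limit estimate.
    """
    if rho is None:
        raise ValueError("a degree distribution is required")
    _check_probability(eps0, "eps0")
    eps = [eps0]
    converged = False
    for _ in range(max_iter):
        nxt = de_step(eps[-1], rho)
        eps.append(nxt)
        if abs(nxt - eps[-2]) < tol:
            converged = True
            break
    return DEResult(tuple(eps), converged, eps[-1], len(eps) - 1, tol)


def first_order_coefficients(rho: DegreeDistribution) -> tuple[float, float]:
    """(constant, linear) coefficients of the recursion expanded in eps.

    The constant term is rho_1 and the linear coefficient rho_2 + 2*rho_3;
    degrees above 3 only contribute at second order.
    """
    return rho.rho(1), rho.rho(2) + 2.0 * rho.rho(3)


@dataclass(frozen=True)
class ResilienceVerdict:
    """First-order resilience diagnostics for a degree distribution."""

    rho1_zero: bool
    linear_ok: bool  # rho_2 + 2*rho_3 < 1
    rho3_ok: bool  # rho_3 < 0.5
    linear_coefficient: float
    error_floor: float | None  # rho_1 / (1 - linear coeff.) when defined
    resilient: bool


def resilience_check(rho: DegreeDistribution) -> ResilienceVerdict:
    """First-order test of whether state disturbances vanish under ``rho``."""
    rho1, linear = first_order_coefficients(rho)
    rho1_zero = rho1 == 0.0
    linear_ok = linear < 1.0
    rho3_ok = rho.rho(3) < 0.5
    floor = rho1 / (1.0 - linear) if linear_ok else None
    return ResilienceVerdict(
        rho1_zero=rho1_zero,
        linear_ok=linear_ok,
        rho3_ok=rho3_ok,
        linear_coefficient=linear,
        error_floor=floor,
        resilient=rho1_zero and linear_ok and rho3_ok,
    )


def critical_degree3_mass(high_degree: int = 6, tol: float = 1e-12) -> float:
    """Supremum of the degree-3 edge fraction compatible with vanishing errors.

    With no degree-1 or degree-2 mass, splits the distribution between
    degree 3 and a single high degree and solves (by bracketing) for the
    rho_3 at which the linear coefficient of the first-order expansion
    reaches 1 — beyond it, the recursion cannot contract near zero.
    """
    if high_degree <= 3:
        raise ValueError("the balancing degree must exceed 3")

    def excess(r3: float) -> float:
        rho = DegreeDistribution({3: r3, high_degree: 1.0 - r3})
        _, linear = first_order_coefficients(rho)
        return linear - 1.0

    return float(brentq(excess, 1e-9, 1.0 - 1e-9, xtol=tol))


def simulate_de_round(
    rho: DegreeDistribution,
    eps: float,
    n_samples: int,
    rng: np.random.Generator | int,
) -> float:
    """Monte-Carlo estimate of one recursion round, from actual bit operations.

    Samples control nodes with degree drawn edge-perspective from ``rho``.
    For each node: a uniform child state and, per comparison, a uniform
    regulator state and sign; each message is independently flipped with
    probability ``eps`` (every comparison receives an independent copy of
    the child message — the independence idealization of the analysis);
    the pairwise truth-table output is computed for true and perturbed
    messages and the node errs when at least half of its comparisons do,
    ties counted as errors.  The mean error frequency estimates
    ``de_step(eps, rho)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    degrees = np.array(rho.degrees())
    weights = np.array([rho.rho(j) for j in degrees])
    sampled = rng.choice(degrees, size=n_samples, p=weights / weights.sum())
    errors = 0
    for j in sampled:
        m = int(j) - 1
        if m == 0:
            errors += 1  # empty majority: the node's own error persists
            continue
        child = rng.integers(0, 2, size=m)
        parent = rng.integers(0, 2, size=m)
        inhibit = rng.random(m) < 0.5
        child_flip = rng.random(m) < eps
        parent_flip = rng.random(m) < eps
        child_p = child ^ child_flip
        parent_p = parent ^ parent_flip
        true_out = np.where(inhibit, (parent ^ child) & child, parent | child)
        pert_out = np.where(inhibit, (parent_p ^ child_p) & child_p, parent_p | child_p)
        wrong = int((true_out != pert_out).sum())
        if wrong >= math.ceil(m / 2):
            errors += 1
    return errors / n_samples
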