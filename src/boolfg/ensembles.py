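"""Random Boolean network ensembles and the connectivity/attractor experiment.

Networks are sampled with a prescribed average control-node degree: each
gene's control node draws its degree (regulators + the own-child edge) from
a shifted binomial on {1, ..., n}, rejection-sampled so the realized mean
stays within a tolerance of the target.  Regulators are distinct genes
sampled uniformly (self-regulation excluded by default) and each edge is
independently an activation with probability ``sign_probability``.

The connectivity experiment mirrors the homeostatic-stability analysis:
for each average-degree setting, sample many 10-node networks, enumerate
all 2^10 initial states, and record the number of attractors.  The median
attractor count falls as connectivity rises — denser voting neighborhoods
pull more of the state space into few large basins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import find_attractors
from .network import BooleanNetwork, GeneNode, Interaction, Sign


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of the connectivity experiment."""

    n: int = 10
    networks_per_setting: int = 50
    avg_degree_settings: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    sign_probability: float = 0.5
    rng_seed: int = 0
    allow_self: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("ensemble networks need at least 2 nodes")
        if self.networks_per_setting < 1:
            raise ValueError("need at least one network per setting")
        if any(not 1 <= s <= self.n for s in self.avg_degree_settings):
            raise ValueError("average degree settings must lie in [1, n]")


@dataclass(frozen=True)
class EnsembleResult:
    """Per-setting attractor counts plus boxplot-ready summary statistics."""

    spec: EnsembleSpec
    counts: dict[int, tuple[int, ...]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for setting in sorted(self.counts):
            values = np.asarray(self.counts[setting])
            rows.append(
                {
                    "avg_degree": setting,
                    "median": float(np.median(values)),
                    "q1": float(np.percentile(values, 25)),
                    "q3": float(np.percentile(values, 75)),
                    "min": int(values.min()),
                    "max": int(values.max()),
                }
            )
        return pd.DataFrame(rows)

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            {"avg_degree": setting, "network": i, "n_attractors": c}
            for setting in sorted(self.counts)
            for i, c in enumerate(self.counts[setting])
        ]
        return pd.DataFrame(rows)


def _sample_degrees(
    n: int,
    target: float,
    rng: np.random.Generator,
    max_degree: int,
    tolerance: float = 0.25,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Control-node degrees 1 + Binomial(max_degree - 1, p), mean near target."""
    if target == 1.0:
        return np.ones(n, dtype=np.int64)
    p = (target - 1.0) / (max_degree - 1.0)
    for _ in range(max_tries):
        degrees = 1 + rng.binomial(max_degree - 1, p, size=n)
        if abs(degrees.mean() - target) <= tolerance:
            return degrees
    raise RuntimeError(
        f"could not realize mean control-node degree {target} within +/-{tolerance}"
    )


def sample_random_network(
    n: int,
    target_avg_degree: float,
    rng: np.random.Generator | int,
    sign_probability: float = 0.5,
    allow_self: bool = False,
) -> BooleanNetwork:
    """One random signed network with the prescribed mean control-node degree.

    Control-node degree counts the own-child edge, so a degree-``d`` node has
    ``d - 1`` regulators, drawn uniformly without replacement among the other
    genes (or all genes when ``allow_self``).  Deterministic per seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    max_degree = n + 1 if allow_self else n
    if not 1 <= target_avg_degree <= max_degree:
        raise ValueError(
            f"target average degree {target_avg_degree} infeasible for n={n}"
        )
    degrees = _sample_degrees(n, float(target_avg_degree), rng, max_degree)
    nodes = tuple(GeneNode(f"g{i}") for i in range(n))
    interactions: list[Interaction] = []
    for i in range(n):
        k_i = int(degrees[i]) - 1
        candidates = [j for j in range(n) if allow_self or j != i]
        regulators = rng.choice(len(candidates), size=k_i, replace=False)
        for r in sorted(int(x) for x in regulators):
            source = nodes[candidates[r]].name
            sign = Sign.ACTIVATION if rng.random() < sign_probability else Sign.INHIBITION
            interactions.append(Interaction(source, nodes[i].name, sign))
    return BooleanNetwork(nodes, tuple(interactions))


def attractor_count_experiment(spec: EnsembleSpec) -> EnsembleResult:
    """Run the connectivity-vs-attractor-count experiment for ``spec``.

    Fully reproducible from ``spec.rng_seed``: every sampled network gets an
    independent child stream of the seed sequence.
    """
    counts: dict[int, tuple[int, ...]] = {}
    for setting in spec.avg_degree_settings:
        seq = np.random.SeedSequence(entropy=spec.rng_seed, spawn_key=(setting,))
        children = seq.spawn(spec.networks_per_setting)
        setting_counts = []
        for child in children:
            rng = np.random.default_rng(child)
            net = sample_random_network(
                spec.n,
                setting,
                rng,
                sign_probability=spec.sign_probability,
                allow_self=spec.allow_self,
            )
            setting_counts.append(len(find_attractors(net)))
        counts[setting] = tuple(setting_counts)
    return EnsembleResult(spec, counts)
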