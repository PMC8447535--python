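"""Density evolution: does a random state disturbance heal or persist?

Iterates the error-probability recursion eps_l = f(eps_{l-1}) from an
initial disturbance eps_0 = 0.25 for several control-node degree
distributions rho(x), prints the limiting error, and checks the
first-order resilience conditions (rho_1 = 0, rho_2 + 2*rho_3 < 1,
rho_3 < 0.5).  A Monte-Carlo bit-level simulation of a single round
cross-checks the recursion.
"""

import numpy as np

from boolfg import (
    DegreeDistribution,
    de_evolve,
    de_step,
    degree_distribution,
    li_yeast_network,
    resilience_check,
    simulate_de_round,
)

cases = {
    "rho(x) = x (no regulators)": DegreeDistribution({1: 1.0}),
    "rho(x) = x^3": DegreeDistribution({3: 1.0}),
    "rho(x) = x^5": DegreeDistribution({5: 1.0}),
    "yeast network": degree_distribution(li_yeast_network()),
}

for name, rho in cases.items():
    result = de_evolve(0.25, rho)
    verdict = resilience_check(rho)
    print(f"{name:28s} limit eps = {result.limit:.6g}   "
          f"resilient: {'yes' if verdict.resilient else 'no'}")

li = cases["yeast network"]
mc = simulate_de_round(li, 0.25, 100_000, np.random.default_rng(0))
print(f"\nyeast, one round: predicted {de_step(0.25, li):.4f}, "
      f"simulated {mc:.4f}")
print("Degree-1 mass (the orphan Cln3 node) pins a persistent error floor; "
      "pure\nhigh-degree distributions drive the disturbance to zero.")
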