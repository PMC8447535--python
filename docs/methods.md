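# Methods

## Model

A network is a set of named binary nodes with signed directed interactions
and an optional per-node self-degradation flag.  The synchronous update of
gene i proceeds in three stages:

1. **Majority vote.**  Each regulator contributes a signed truth-table
   value computed from its own state and the child's current state
   (activation `p ∨ c`, inhibition `(p ⊕ c) ∧ c`).  Both tables equal the
   child's state when the regulator is inactive, so an inactive regulator
   carries no information; the default vote therefore counts only active
   regulators — A active activators against I active inhibitors — and
   returns 1 if A > I, 0 if I > A, and the current state on a tie
   (including "no active regulators" and "no regulators at all").  This is
   the unique reading that reproduces the yeast trajectories; the literal
   all-regulators vote is available as `strict=True` (CLI
   `--strict-majority`) and is documented as *not* reproducing them
   (e.g. at Start, MBF sees one active activator and one inactive
   inhibitor: abstention turns MBF on, strict counting ties and leaves it
   off).
2. **Clamp enforcement.**  A clamped gene (knockout → 0, over-expression
   → 1) has no control node and holds its clamp.
3. **Self-degradation override.**  A flagged gene that has been active
   with every regulator silent for `t_d` consecutive completed steps is
   forced to 0.  Per-node counters increment on each qualifying step and
   reset otherwise; with the default `t_d = 1` the override fires
   immediately, making the update a pure function of the current state.

Because the counters carry history, trajectory recurrence is detected on
the pair (state, counters).  With `t_d = 1` the successor function is
memoryless (asserted by test), but a trajectory may still repeat its
absorbing state once when the counters differ on first arrival; the
wild-type yeast cycle consequently shows 13 transitions (14 rows) from the
Start excited state back to stationary G1.

## Yeast cell-cycle fixture

The built-in network has 11 nodes in the encoding order Cln3, MBF, SBF,
Cln1,2, Cdh1, Swi5, Cdc20,14, Clb5,6, Sic1, Clb1,2, Mcm1/SFF, with 29
signed interactions and self-degradation on Cln3, Cln1,2, Swi5, Cdc20,14
and Mcm1/SFF (`t_d = 1`).  Self-degradation is a node flag, not an edge:
it does not enter in-degrees or the degree distribution.  The transcription
of the interaction diagram is validated indirectly: the factor-graph degree
distribution must equal
ρ(x) = 0.025x + 0.05x² + 0.3x³ + 0.2x⁴ + 0.125x⁵ + 0.3x⁶ exactly, and the
published wild-type and knockout trajectories must reproduce bit-for-bit —
both are asserted in the test suite.

**Degree convention.**  A control node's factor-graph degree is
`k_i + 1`: its regulator edges plus the edge to its own child variable.
This is the only convention consistent with both the published ρ(x) above
and the density-evolution recursion, whose degree-j node performs a
majority over j − 1 pairwise values.

**Phase labels.**  Labels are assigned by a forward-advancing machine
Start → G1 → S → G2 → M → Stationary G1.  The stationary pattern
(Cdh1 = Sic1 = 1, all else 0, clamps honored) is recognized first;
otherwise: Start while Cln3 is on; G1 after it falls; S on the first step
with Clb5,6 active; G2 once any mitotic marker (Clb1,2, Cdc20,14 or
Mcm1/SFF) is active; M once MBF and SBF are off while Clb1,2 or Cdc20,14
is active.  The Clb1,2 clause in the M marker is deliberate: it lets the
Cdc20,14-deletion arrest (mitotic cyclins high, transcription factors off)
be labeled M, matching the reported telophase block, without disturbing
any other table's terminal phase.  The G1/S boundary and all terminal
phases match the published knockout tables; the S/G2 split inside two
knockout tables differs by one step (those published labels follow no
single marker), which only affects cosmetic mid-trajectory labels, not
viability or arrest calls.

**Knockout conventions.**  Deletion clamps a gene to 0 and removes its
control node; its outgoing edges remain but are inert (a permanently
silent regulator abstains), which the tests show is equivalent to removing
them.  Knockout simulations start from the Start excited state
`10001000100` with clamped bits overridden.  Viability requires visiting
all four phases G1/S/G2/M and resting at the stationary G1 fixed point.
Conflicting clamps: the last applied wins, with a logged warning.

## Attractor search

All 2^n initial states are followed to absorption with memoized successor
lookup; basins are exact and partition the state space.  For `t_d = 1` the
full transition table is built vectorized (numpy) and the functional graph
is resolved by path-following with attractor-id coloring; for `t_d > 1`
a generic memoized traversal runs on augmented (state, counters) pairs.
Exhaustive enumeration is refused above 2^22 states; sample initial states
with `simulate` instead.  Cycles are reported in visit order, rotated to
start at the lexicographically smallest state; attractors sort by
descending basin size.

## Random ensembles

The connectivity experiment samples signed networks with a prescribed mean
control-node degree: degrees are drawn as 1 + Binomial(n − 1, p) with p
matched to the target mean, rejection-sampled to keep the realized mean
within ±0.25 of target (an irregular but reproducible profile); each
node's regulators are distinct uniform draws excluding itself (a flag
permits self-regulation, which is the only way a degree-one gene can
correct its own errors); each edge is an activation with probability 0.5.
Defaults follow the study conditions: 10-node networks, 50 networks per
setting, average degrees 1–8, all 2^10 initial states enumerated per
network.  Runs are reproducible from a single seed via per-setting
spawned seed sequences.  The exact published box statistics depend on an
unspecified sampler and seed, so the assertions cover the analytic
degree-1 case (every state fixed, 2^10 attractors) and the monotone
decrease of the median attractor count; cycle attractors are counted the
same way as fixed points.

## Density evolution

With i.i.d. state errors of probability ε, a single signed pairwise
comparison errs with probability y = ε(1 − ε/2) (a single flipped message
changes the table output with conditional probability 1/2 over uniform
states; so do two flips).  A degree-j control node errs when at least
⌈(j−1)/2⌉ of its j − 1 comparisons err — the binomial upper tail,
evaluated exactly with integer binomial coefficients (`math.comb`),
including the exact-tie term as printed; at j = 1 the empty majority
evaluates to 1, the constant ρ₁ term of the first-order expansion
ε_l ≈ ρ₁ + (ρ₂ + 2ρ₃)ε_{l−1}.  Note the analysis counts ties as errors
while the simulator's tie rule keeps the current state; the two
conventions are implemented as stated and not conflated.  Iteration stops
when successive values differ by less than `tol` (default 1e-12, max 500
iterations); the full sequence is reported so non-monotone behavior stays
visible.  The critical degree-3 bound is obtained numerically by
bracketing the ρ₃ at which the linear coefficient reaches 1 (ρ₁ = ρ₂ = 0,
remaining mass at a degree > 3), giving 0.5.

The Monte-Carlo cross-check simulates one round at the bit level under the
analysis' independence idealization: control-node degrees drawn
edge-perspective from ρ, uniform true states, independent message flips,
and an independent copy of the child message per comparison.  The last
point matters: with a physically shared child message the per-comparison
error indicators are correlated and the binomial tail is not their exact
law, which is precisely the locally-tree-like approximation the recursion
makes.  Passing this check therefore validates the implementation of the
recursion, not the recursion's fidelity on short-loop graphs.

## Synthetic data and scope

All test inputs are generated in code: the built-in yeast fixture, the
published trajectory tables (transcribed as bitstring constants), and the
random-network sampler.  The sampler emulates size and degree structure
only — it has no autoregulation, no degree correlations, and no
scale-free tails, so ensemble results say nothing about those features of
real regulatory networks.  Problem sizes follow the study conditions
(2^11-state yeast enumeration, 50 × 8 ten-node ensembles, 100 eight-node
networks for the basin-partition property); the whole suite runs in a few
seconds.  Asynchronous schedules, multi-valued logic, edge-level
perturbations and inference from expression data are out of scope.
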