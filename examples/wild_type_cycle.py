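"""Simulate one wild-type division cycle of the budding-yeast network.

The cell-size signal switches Cln3 on in the resting G1 state; the network
then traverses Start, G1, S, G2 and M in 13 synchronous transitions before
settling back at the stationary G1 fixed point.
"""

from boolfg import YEAST_START_STATE, is_viable, labeled_trajectory, li_yeast_network

net = li_yeast_network()
traj = labeled_trajectory(net, YEAST_START_STATE)

print("time  state        phase")
for t, (state, phase) in enumerate(zip(traj.states, traj.phases), start=1):
    print(f"{t:4d}  {state.to_bitstring()}  {phase}")

print(f"\n{traj.transitions} transitions, terminal {traj.terminal}, "
      f"viable: {is_viable(traj, net)}")
print("Each row is the 11-gene state (order: Cln3, MBF, SBF, Cln1,2, Cdh1, "
      "Swi5,\nCdc20,14, Clb5,6, Sic1, Clb1,2, Mcm1/SFF); the phase column "
      "tracks the\ncell-cycle stage implied by the marker genes.")
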