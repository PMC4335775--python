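"""Simulate the wildtype cell cycle and check it against the target sequence.

Prints the ten-state trajectory under synchronous updating, the phase label
of each state, and whether the final state is a fixed point.
"""

from pombenet import UpdateScheme, simulate, wildtype, cell_cycle_sequence

net = wildtype()
seq = cell_cycle_sequence()
traj = simulate(net, seq[0], steps=9, scheme=UpdateScheme("parallel"))

for t, (state, phase) in enumerate(zip(traj, seq.phases), start=1):
    mark = "ok" if state == seq[t - 1] else "MISMATCH"
    print(f"t={t:2d}  {''.join(map(str, state))}  {phase:5s}  {mark}")

g1 = traj[-1]
print("G1 is a fixed point:", simulate(net, g1, 1, UpdateScheme("parallel"))[1] == g1)
# each line shows one time step; "ok" means the simulated state equals the
# printed cell-cycle state for that step.
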