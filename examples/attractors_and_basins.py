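"""Enumerate the wildtype's attractors under each deterministic scheme.

For each scheme the full 1024-state transition graph is built, and the
attractors with their basin sizes are listed; the G1 basin dominates the
state space (762/1024 under parallel updating).
"""

from pombenet import UpdateScheme, build_transition_graph, find_attractors, wildtype
from pombenet.analysis import default_scheme
from pombenet.fission_yeast import g1_index

net = wildtype()
g1 = g1_index()
for mode in ("parallel", "sequential", "block_sequential"):
    att = find_attractors(build_transition_graph(net, default_scheme(mode)))
    print(f"\n{mode}: {len(att.fixed_points)} fixed points, "
          f"{len(att.limit_cycles)} limit cycles")
    for a, size in sorted(att.basin_sizes().items(), key=lambda kv: -kv[1])[:3]:
        label = " (G1)" if g1 in a else ""
        print(f"  attractor {a} basin {size}{label}")
# basin sizes always sum to 1024; the set of fixed points is the same for
# every deterministic scheme, while limit cycles and basins change.
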