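"""Monte-Carlo absorption into G1 under fully asynchronous updating.

Each trajectory updates one uniformly random node per step. The expected
basin mass of G1 is the sum over all 1024 initial states of the fraction of
runs absorbed at G1 — under random updating G1 loses its dominance.
"""

from pombenet import estimate_async_basin, wildtype
from pombenet.fission_yeast import g1_index

probs, mass = estimate_async_basin(wildtype(), g1_index(), runs=20, seed=1)
print(f"expected G1 basin mass (async): {mass:.1f} of 1024 states")
print(f"states absorbed with certainty: {(probs == 1.0).sum()}")
print(f"states never absorbed:          {(probs == 0.0).sum()}")
# compare mass with the deterministic parallel basin of 762: random update
# order spreads the initial states over many attractors.
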