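# Methods

## Dynamics

Every operation is built on one local rule: node `i` turns on when the
weighted sum of its inputs strictly exceeds its threshold, turns off when
strictly below, and keeps its previous value on an exact tie. Because
thresholds may be half-integers, they are stored internally as doubled
integers and compared against the doubled weighted sum — the tie case is an
exact integer equality, never a floating-point comparison. The hold-on-tie
convention is load-bearing: with it the wildtype reproduces the ten-state
cell-cycle trajectory bit for bit and the G1 basin comes out at exactly
762/1024 states; a strict or zero-on-tie variant does neither.

Updating schemes. Parallel updates all nodes simultaneously; sequential
performs one full sweep in a fixed node order, each node seeing
already-updated values; block-sequential updates blocks in order,
synchronously within a block; deterministic-asynchronous updates the single
next node of a fixed order per time step; fully-asynchronous updates one
uniformly random node per step. State-transition graphs are defined only for
the deterministic schemes, with one graph edge corresponding to one full
sweep for the (block-)sequential schemes, so each scheme yields a single
total successor map over the `2^n` states. The deterministic-asynchronous
scheme is likewise composed into a full sweep when a transition graph is
requested (per-step it is not a total map into distinct states), which makes
its macro-dynamics coincide with the sequential scheme of the same order.

Attractors are found by following every orbit once (each state is visited a
constant number of times, so the whole 1024-state analysis runs in
milliseconds); a cycle of length 1 is a fixed point, longer cycles are limit
cycles, and a state's basin is the attractor its orbit reaches, with the
attractor's own states counted as basin members. That inclusive convention
is what yields 762 for the wildtype G1 basin. Fixed points are invariant
across all updating schemes (a state no single-node update can leave is
fixed under every discipline); the test suite asserts this on the wildtype
and on random small networks.

Fully-asynchronous basins have no exact finite description, so they are
estimated by Monte Carlo: from each of the `2^n` initial states a fixed
number of independent trajectories is run, each stopping on hitting any
fixed point or after `100·n` single-node updates (absorption in this 10-node
model is far faster, so the cap is safely slack). The per-state absorption
probability at the G1 fixed point and its sum (the expected basin mass) are
reported; the whole estimate is reproducible from one seed.

## The wildtype model

The packaged wildtype (`data/wildtype.json`) is the 10-node fission-yeast
cell-cycle threshold network: unit-magnitude signed weights, 27 edges
(8 activating, 19 inhibiting, four self-degradation loops on Start, SK,
Slp1 and PP), thresholds zero everywhere except −½ on Cdc2/Cdc13 (active by
default unless inhibited) and +½ on Cdc2/Cdc13\* (needs net activation).
The parameters live in a versioned data file rather than in code, and their
correctness is enforced by three independent computations in the test suite:
the exact ten-state trajectory, the 762-state G1 basin, and the 27/8/19 edge
counts. An alternative parameterisation (doubled Slp1→Cdc2/Cdc13\* weight
with a zero threshold) also replays the trajectory but yields a basin of
818, so the basin size pins the transcription uniquely.

## Fitness and the evolution strategy

Fitness of a genotype (W, Θ) is the mean absolute deviation between the
parallel one-step image of each of the ten target states and its expected
successor, normalised by the `10·n` target bits. A ten-row trajectory has
nine transitions; the tenth target is the G1 self-transition, which also
enforces the fixed-point property — so fitness 0 is exactly "replays the
cell cycle and rests at G1". Only the zero set of the fitness matters for
harvesting; any monotone variant would select the same functional networks.

The strategy is mutation-only, with the defaults as study conditions:
population 20, elite fraction 20 % (4 elites), iteration cap 100. Initial
candidates perturb the wildtype with `ngh` single-weight edits (nonzero → 0,
zero → uniform nonzero) plus `ngh` threshold redraws from the 7-value set,
`ngh` uniform on [1, 30]. Each generation keeps the elites (stable ranking,
ties by insertion order, so reruns are bit-identical), breeds 8 mutants —
one weight edit and one threshold edit of a uniformly chosen elite, chosen
with replacement — and refills with 8 fresh wildtype perturbations. Elitism
makes the best fitness non-increasing, which the tests assert.

Harvesting runs the strategy to completion repeatedly, taking at most one
functional network per run (a restart policy, so no single run's
neighbourhood is over-represented) and deduplicating exact (W, Θ) pairs;
the wildtype itself, functional by definition, is the first member. Run `k`
uses the RNG stream spawned from the root seed with spawn key `(k,)`, so a
harvest is a pure function of (count, config, seed).

## Neutral graph and analyses

Genotype distance counts the parameters at which two genotypes differ. The
default domain is the concatenated genotype — all `n²` weights plus the `n`
thresholds — since the mutation operator edits both; a `matrix_only` mode
restricts the count to the weight matrix for the narrower reading. Distinct
genotypes therefore never sit at distance 0, and an edge joins two nodes
exactly at distance 1. Construction is all-pairs, chunked, `O(N²·n²)`;
at `n = 10` a 10⁴-network graph is well within reach and no spatial index is
warranted. Path lengths inside the wildtype component come from BFS and can
only exceed the raw genotype distance (each edge changes one parameter);
outside the component the raw distance is the comparable quantity.

Analyses report, per group (wildtype component vs rest): edge-count
histograms (unit-width integer bins over [0, n²]) for total, positive and
negative edges; per-position edge frequencies, with "the activator of node
X" operationalised as any positive inbound weight in row X; and the G1
basin measure per updating scheme — exact basin size for deterministic
schemes, Monte-Carlo expected mass for the fully asynchronous one (20-bin
histograms over [0, 1024]). Group differences are reported descriptively
(medians, IQRs, histograms); a two-sample Kolmogorov–Smirnov statistic is
available as an optional, clearly-labelled add-on rather than a committed
inferential claim.

## Problem sizes and reproducibility

The packaged analyses run harvests of 100–200 networks (the examples use
100, the test suite and acceptance script 200); a 200-network harvest takes
on the order of ten seconds on one core. At that scale the wildtype
component typically holds a large fraction of the harvest — a full-size
harvest of 10⁴ networks finds proportionally many more distant functional
networks, so component-share percentages are scale-dependent and only the
within-component regularities (conserved activators, basin concentration
near 762) are stable observables. All randomness flows from explicit root
seeds; identical seeds reproduce harvests, Monte-Carlo basins and report
files byte for byte.

## Known limitations

* The fitness only constrains the ten target transitions; the other
  `2^10 − 10` states are unconstrained, so "functional" networks may differ
  arbitrarily elsewhere in state space.
* The fully-asynchronous basin is a Monte-Carlo estimate; its variance falls
  as 1/runs and trajectories are capped, so extremely slow-mixing networks
  (not observed in this family) could be under-absorbed.
* The neutral graph is built from the harvested sample, not the full neutral
  space; component membership of a genotype can change as the sample grows,
  though membership is monotone (edges are only ever added).
* No visual rendering of transition or neutral graphs is provided; exports
  are GraphML and TSV for external tools.
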