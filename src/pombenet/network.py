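"""Threshold Boolean network dynamics.

A threshold Boolean network over ``n`` binary nodes is parameterised by an
integer weight matrix ``W`` (entry ``W[i, j]`` is the weight of the edge from
node ``j`` into node ``i``) and a per-node activation threshold vector ``Θ``.
A node updates to 1 when its weighted input sum strictly exceeds its
threshold, to 0 when strictly below, and *holds its previous value on a tie*.
Thresholds may be half-integers; to keep the comparison exact the thresholds
are stored internally as doubled integers and compared against the doubled
weighted sum, so no floating-point tolerance is ever involved.

The module provides the local rule, the five classical updating schemes
(parallel, sequential, block-sequential, deterministic asynchronous and fully
asynchronous), trajectory simulation, exhaustive state-transition graphs for
the deterministic schemes, attractor/basin extraction, and a Monte-Carlo
absorption estimator for the fully asynchronous scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "WEIGHT_VALUES",
    "THETA_VALUES",
    "ThresholdNetwork",
    "UpdateScheme",
    "TransitionGraph",
    "AttractorSet",
    "state_to_index",
    "index_to_state",
    "local_update",
    "scheme_step",
    "simulate",
    "build_transition_graph",
    "find_attractors",
    "basin_size",
    "estimate_async_basin",
]

#: Allowed weight-matrix entries.
WEIGHT_VALUES: tuple[int, ...] = (-2, -1, 0, 1, 2)

#: Allowed threshold values (halves permitted).
THETA_VALUES: tuple[Fraction, ...] = tuple(
    Fraction(v, 2) for v in (-4, -2, -1, 0, 1, 2, 4)
)

_DETERMINISTIC_MODES = ("parallel", "sequential", "block_sequential", "async_deterministic")
_ALL_MODES = _DETERMINISTIC_MODES + ("fully_async",)


def _as_theta2(theta: Sequence) -> np.ndarray:
    """Convert a threshold vector (possibly containing halves) to doubled ints."""
    theta2 = []
    for v in theta:
        d = Fraction(v).limit_denominator(2) * 2
        if d != Fraction(v) * 2 or d.denominator != 1:
            raise ValueError(f"threshold {v!r} is not an integer or half-integer")
        theta2.append(int(d))
    return np.asarray(theta2, dtype=np.int64)


@dataclass(frozen=True)
class ThresholdNetwork:
    """A threshold Boolean network: node labels, weights ``W`` and thresholds ``Θ``.

    ``W[i, j]`` weights the edge from node ``j`` into node ``i``.  Negative
    diagonal entries encode self-degradation.  ``theta2`` holds the thresholds
    doubled so that every activation comparison is exact integer arithmetic.
    """

    labels: tuple[str, ...]
    W: np.ndarray
    theta2: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.int64)
        theta2 = np.asarray(self.theta2, dtype=np.int64)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "theta2", theta2)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("node labels must be unique")
        if W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {W.shape}")
        if theta2.shape != (n,):
            raise ValueError(f"theta must have length {n}, got {theta2.shape}")
        if not np.isin(W, WEIGHT_VALUES).all():
            bad = W[~np.isin(W, WEIGHT_VALUES)][0]
            raise ValueError(f"weight entry {bad} outside allowed set {WEIGHT_VALUES}")
        allowed2 = [int(t * 2) for t in THETA_VALUES]
        if not np.isin(theta2, allowed2).all():
            bad = theta2[~np.isin(theta2, allowed2)][0]
            raise ValueError(f"threshold {bad / 2} outside allowed set")
        W.setflags(write=False)
        theta2.setflags(write=False)

    @classmethod
    def from_theta(
        cls, labels: Sequence[str], W: Sequence[Sequence[int]], theta: Sequence
    ) -> "ThresholdNetwork":
        """Build a network from thresholds given on their natural (half-unit) scale."""
        return cls(tuple(labels), np.asarray(W, dtype=np.int64), _as_theta2(theta))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def theta(self) -> tuple[Fraction, ...]:
        """Thresholds on their natural scale, as exact rationals."""
        return tuple(Fraction(int(t), 2) for t in self.theta2)

    def genotype_key(self) -> bytes:
        """Hashable exact identity of the (W, Θ) parameter pair."""
        return self.W.tobytes() + self.theta2.tobytes()


@dataclass(frozen=True)
class UpdateScheme:
    """One of the five updating disciplines.

    ``order`` is required for the sequential and deterministic-asynchronous
    modes, ``blocks`` for block-sequential.  The fully asynchronous mode draws
    one uniform node per step from an external RNG.
    """

    mode: str
    order: tuple[int, ...] | None = None
    blocks: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in _ALL_MODES:
            raise ValueError(f"unknown update mode {self.mode!r}; choose from {_ALL_MODES}")
        if self.order is not None:
            object.__setattr__(self, "order", tuple(int(i) for i in self.order))
        if self.blocks is not None:
            object.__setattr__(
                self, "blocks", tuple(tuple(int(i) for i in b) for b in self.blocks)
            )

    @property
    def deterministic(self) -> bool:
        return self.mode != "fully_async"

    def validate_for(self, n: int) -> None:
        if self.mode in ("sequential", "async_deterministic"):
            if self.order is None or sorted(self.order) != list(range(n)):
                raise ValueError(f"mode {self.mode!r} needs a full node permutation 'order'")
        if self.mode == "block_sequential":
            if self.blocks is None:
                raise ValueError("block_sequential needs 'blocks'")
            flat = [i for b in self.blocks for i in b]
            if any(len(b) == 0 for b in self.blocks) or sorted(flat) != list(range(n)):
                raise ValueError("blocks must be nonempty, disjoint and cover all nodes")


# ---------------------------------------------------------------------------
# state encoding

def state_to_index(bits: Sequence[int]) -> int:
    """Encode a bit vector as an integer; node 0 is the most significant bit."""
    idx = 0
    for b in bits:
        idx = (idx << 1) | int(b)
    return idx


def index_to_state(index: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`state_to_index`."""
    if not 0 <= index < (1 << n):
        raise ValueError(f"state index {index} out of range for n={n}")
    return tuple((index >> (n - 1 - i)) & 1 for i in range(n))


def _all_states(n: int) -> np.ndarray:
    """(2**n, n) matrix of every state, row ``s`` = bits of index ``s``."""
    idx = np.arange(1 << n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1, dtype=np.int64)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int64)


def _encode_rows(states: np.ndarray) -> np.ndarray:
    n = states.shape[1]
    weights = 1 << np.arange(n - 1, -1, -1, dtype=np.int64)
    return states @ weights


# ---------------------------------------------------------------------------
# dynamics

def local_update(net: ThresholdNetwork, state: Sequence[int], i: int) -> int:
    """New value of node ``i``: 1 if ΣW[i,j]·x_j > θ_i, 0 if below, hold on tie."""
    if not 0 <= i < net.n:
        raise IndexError(f"node index {i} out of range for n={net.n}")
    x = np.asarray(state, dtype=np.int64)
    if x.shape != (net.n,):
        raise ValueError(f"state length {x.shape} does not match n={net.n}")
    s2 = 2 * int(net.W[i] @ x)
    if s2 > net.theta2[i]:
        return 1
    if s2 < net.theta2[i]:
        return 0
    return int(x[i])


def _update_nodes(net: ThresholdNetwork, states: np.ndarray, nodes) -> np.ndarray:
    """Simultaneously recompute columns ``nodes`` of a (m, n) batch of states."""
    nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
    s2 = 2 * states @ net.W[nodes].T          # (m, len(nodes))
    th = net.theta2[nodes][None, :]
    out = states.copy()
    out[:, nodes] = np.where(s2 > th, 1, np.where(s2 < th, 0, states[:, nodes]))
    return out


def parallel_step_batch(net: ThresholdNetwork, states: np.ndarray) -> np.ndarray:
    """Synchronous image of each row of a (m, n) batch of states."""
    return _update_nodes(net, states, np.arange(net.n))


def scheme_step(
    net: ThresholdNetwork,
    state: Sequence[int],
    scheme: UpdateScheme,
    rng: np.random.Generator | None = None,
    t: int = 0,
) -> tuple[int, ...]:
    """One time step of ``scheme`` applied to ``state``.

    For the sequential and block-sequential modes a step is one full sweep.
    The deterministic-asynchronous mode updates the single node
    ``order[t mod n]``; the fully asynchronous mode updates one node drawn
    uniformly from ``rng`` (required).
    """
    scheme.validate_for(net.n)
    x = np.asarray(state, dtype=np.int64)[None, :]
    if x.shape[1] != net.n:
        raise ValueError(f"state length {x.shape[1]} does not match n={net.n}")
    if scheme.mode == "parallel":
        x = parallel_step_batch(net, x)
    elif scheme.mode == "sequential":
        for i in scheme.order:
            x = _update_nodes(net, x, i)
    elif scheme.mode == "block_sequential":
        for block in scheme.blocks:
            x = _update_nodes(net, x, list(block))
    elif scheme.mode == "async_deterministic":
        x = _update_nodes(net, x, scheme.order[t % net.n])
    else:  # fully_async
        if rng is None:
            raise ValueError("fully_async updating requires an rng")
        x = _update_nodes(net, x, int(rng.integers(net.n)))
    return tuple(int(b) for b in x[0])


def simulate(
    net: ThresholdNetwork,
    init: Sequence[int],
    steps: int,
    scheme: UpdateScheme,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, ...]]:
    """Trajectory of ``steps + 1`` states starting at ``init``."""
    if steps < 0:
        raise ValueError("steps must be non-negative")
    traj = [tuple(int(b) for b in init)]
    for k in range(steps):
        traj.append(scheme_step(net, traj[-1], scheme, rng=rng, t=k))
    return traj


# ---------------------------------------------------------------------------
# exhaustive state-transition graphs, attractors, basins

@dataclass(frozen=True)
class TransitionGraph:
    """Deterministic successor map over all 2**n states (out-degree exactly 1)."""

    successor: np.ndarray
    scheme: UpdateScheme
    n: int

    @property
    def n_states(self) -> int:
        return 1 << self.n


def build_transition_graph(net: ThresholdNetwork, scheme: UpdateScheme) -> TransitionGraph:
    """Successor of every state under a deterministic scheme.

    For the sequential and block-sequential modes one edge is one complete
    sweep over all nodes/blocks; the deterministic-asynchronous mode is
    likewise composed into a full sweep over ``order`` so that each state has
    a single well-defined successor.
    """
    if not scheme.deterministic:
        raise ValueError("transition graphs are defined only for deterministic schemes")
    scheme.validate_for(net.n)
    states = _all_states(net.n)
    if scheme.mode == "parallel":
        out = parallel_step_batch(net, states)
    elif scheme.mode in ("sequential", "async_deterministic"):
        out = states
        for i in scheme.order:
            out = _update_nodes(net, out, i)
    else:  # block_sequential
        out = states
        for block in scheme.blocks:
            out = _update_nodes(net, out, list(block))
    return TransitionGraph(successor=_encode_rows(out), scheme=scheme, n=net.n)


@dataclass(frozen=True)
class AttractorSet:
    """Attractors of a deterministic transition graph and their basins.

    ``attractors`` lists each attractor as a tuple of state indices in cycle
    order (length 1 = fixed point, length p > 1 = limit cycle of period p);
    ``attractor_of[s]`` is the attractor index state ``s`` eventually reaches.
    """

    attractors: tuple[tuple[int, ...], ...]
    attractor_of: np.ndarray

    @property
    def fixed_points(self) -> list[int]:
        return [a[0] for a in self.attractors if len(a) == 1]

    @property
    def limit_cycles(self) -> list[tuple[int, ...]]:
        return [a for a in self.attractors if len(a) > 1]

    @property
    def basin(self) -> dict[tuple[int, ...], frozenset[int]]:
        """Map attractor → set of states whose orbit reaches it (attractor included)."""
        out = {}
        for aid, att in enumerate(self.attractors):
            out[att] = frozenset(np.flatnonzero(self.attractor_of == aid).tolist())
        return out

    def basin_sizes(self) -> dict[tuple[int, ...], int]:
        counts = np.bincount(self.attractor_of, minlength=len(self.attractors))
        return {att: int(counts[aid]) for aid, att in enumerate(self.attractors)}


def find_attractors(tg: TransitionGraph) -> AttractorSet:
    """Fixed points, limit cycles and basins by following every orbit once."""
    succ = tg.successor
    n_states = tg.n_states
    color = np.zeros(n_states, dtype=np.int8)  # 0 new, 1 on current path, 2 resolved
    attr_of = np.full(n_states, -1, dtype=np.int64)
    attractors: list[tuple[int, ...]] = []
    for s in range(n_states):
        if color[s] == 2:
            continue
        path = []
        cur = s
        while color[cur] == 0:
            color[cur] = 1
            path.append(cur)
            cur = int(succ[cur])
        if color[cur] == 1:  # closed a new cycle on this path
            start = path.index(cur)
            cycle = tuple(path[start:])
            aid = len(attractors)
            attractors.append(cycle)
            for c in cycle:
                attr_of[c] = aid
        aid = int(attr_of[cur])
        for p in path:
            attr_of[p] = aid
            color[p] = 2
    return AttractorSet(attractors=tuple(attractors), attractor_of=attr_of)


def basin_size(attractors: AttractorSet, target: int) -> int:
    """Number of states whose orbit reaches the attractor containing ``target``.

    ``target`` must itself be an attractor state; the attractor's own states
    count toward the basin.
    """
    for aid, att in enumerate(attractors.attractors):
        if target in att:
            return int((attractors.attractor_of == aid).sum())
    raise ValueError(f"state {target} is not an attractor state")


# ---------------------------------------------------------------------------
# fully asynchronous absorption

def fixed_points_mask(net: ThresholdNetwork) -> np.ndarray:
    """Boolean mask over all 2**n states marking the (scheme-invariant) fixed points."""
    states = _all_states(net.n)
    return (parallel_step_batch(net, states) == states).all(axis=1)


def estimate_async_basin(
    net: ThresholdNetwork,
    target: int,
    runs: int,
    max_steps: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, float]:
    """Monte-Carlo absorption probabilities under fully asynchronous updating.

    From every initial state, ``runs`` independent trajectories are simulated,
    each updating one uniformly random node per step, stopping on hitting any
    fixed point or after ``max_steps`` single-node updates (default 100·n).
    Returns the per-state fraction of trajectories absorbed at ``target`` and
    the expected basin mass (the sum of those fractions).
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    n = net.n
    if max_steps is None:
        max_steps = 100 * n
    fixed = fixed_points_mask(net)
    if not fixed[target]:
        raise ValueError(f"state {target} is not a fixed point")
    rng = np.random.default_rng(seed)
    n_states = 1 << n
    hits = np.zeros(n_states, dtype=np.int64)
    init = _all_states(n)
    for _ in range(runs):
        states = init.copy()
        idx = _encode_rows(states)
        active = ~fixed[idx]
        for _ in range(max_steps):
            if not active.any():
                break
            act = np.flatnonzero(active)
            nodes = rng.integers(n, size=act.size)
            sub = states[act]
            s2 = 2 * np.einsum("ij,ij->i", net.W[nodes], sub)
            th = net.theta2[nodes]
            old = sub[np.arange(act.size), nodes]
            new = np.where(s2 > th, 1, np.where(s2 < th, 0, old))
            states[act, nodes] = new
            idx[act] = _encode_rows(states[act])
            active[act] = ~fixed[idx[act]]
        hits += idx == target
    probs = hits / runs
    return probs, float(probs.sum())
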