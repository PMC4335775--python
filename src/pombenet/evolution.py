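"""Evolution strategy for harvesting functional cell-cycle networks.

The search space is the genotype (W, Θ) of a 10-node threshold network, with
weights in {−2, −1, 0, 1, 2} and thresholds in {−2, −1, −½, 0, ½, 1, 2}.  A
genotype is *functional* when its synchronous dynamics reproduces all ten
target transitions of the cell-cycle sequence (the tenth being the G1
self-transition, which enforces the fixed point).  Fitness is the mean
absolute deviation between the one-step image of each target row and the
expected next row, so fitness 0 ⇔ functional.

The strategy is mutation-only: an initial population of wildtype
perturbations (ngh weight edits + ngh threshold edits, ngh ~ U[1, 30]), then
per generation rank ascending by fitness, keep the top m% unchanged, breed
half of the remainder by a single weight edit plus a single threshold edit of
a random elite, and refill the other half with fresh wildtype perturbations.
A run succeeds when any candidate hits fitness 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .fission_yeast import TargetSequence, cell_cycle_sequence, wildtype
from .network import ThresholdNetwork

__all__ = [
    "Genotype",
    "ESConfig",
    "Candidate",
    "rule1",
    "rule2",
    "initial_candidate",
    "fitness",
    "evolve_generation",
    "run_es",
    "harvest",
]

log = logging.getLogger(__name__)

_NONZERO_WEIGHTS = np.array([-2, -1, 1, 2], dtype=np.int64)
_THETA2_VALUES = np.array([-4, -2, -1, 0, 1, 2, 4], dtype=np.int64)


@dataclass(frozen=True)
class Genotype:
    """A candidate parameter pair (W, doubled thresholds)."""

    W: np.ndarray
    theta2: np.ndarray

    def __post_init__(self) -> None:
        W = np.ascontiguousarray(self.W, dtype=np.int64)
        t2 = np.ascontiguousarray(self.theta2, dtype=np.int64)
        W.setflags(write=False)
        t2.setflags(write=False)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "theta2", t2)

    @classmethod
    def of(cls, net: ThresholdNetwork) -> "Genotype":
        return cls(net.W, net.theta2)

    def to_network(self, labels: tuple[str, ...]) -> ThresholdNetwork:
        return ThresholdNetwork(labels, self.W, self.theta2)

    def key(self) -> bytes:
        return self.W.tobytes() + self.theta2.tobytes()

    def __eq__(self, other) -> bool:
        return isinstance(other, Genotype) and self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())


@dataclass(frozen=True)
class ESConfig:
    """Evolution-strategy parameters (defaults are the study conditions)."""

    pop_size: int = 20
    elite_frac: float = 0.2
    max_iters: int = 100
    ngh_range: tuple[int, int] = (1, 30)

    def __post_init__(self) -> None:
        if self.n_elites < 1:
            raise ValueError("pop_size * elite_frac must round to at least one elite")
        if (self.pop_size - self.n_elites) % 2 != 0:
            raise ValueError(
                "pop_size minus elites must be even (mutants and random refill split equally)"
            )
        lo, hi = self.ngh_range
        if not 1 <= lo <= hi:
            raise ValueError("ngh_range must satisfy 1 <= lo <= hi")

    @property
    def n_elites(self) -> int:
        return round(self.pop_size * self.elite_frac)

    @property
    def n_mutants(self) -> int:
        return (self.pop_size - self.n_elites) // 2


@dataclass(frozen=True)
class Candidate:
    genotype: Genotype
    mismatches: int  # raw deviating bits over the 10·n targets
    n: int

    @property
    def fitness(self) -> float:
        return self.mismatches / (10 * self.n)

    @property
    def functional(self) -> bool:
        return self.mismatches == 0


# ---------------------------------------------------------------------------
# mutation rules

def rule1(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Edit one uniformly chosen weight: nonzero → 0, zero → uniform nonzero.

    The chosen entry always changes, so the result is at W-Hamming distance
    exactly 1 from the input.
    """
    n2 = W.size
    flat = int(rng.integers(n2))
    i, j = divmod(flat, W.shape[1])
    out = np.array(W, dtype=np.int64)
    if out[i, j] != 0:
        out[i, j] = 0
    else:
        out[i, j] = int(rng.choice(_NONZERO_WEIGHTS))
    return out


def rule2(theta2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace one uniformly chosen threshold by a uniform draw from the 7-value set.

    The draw may coincide with the old value, so the Θ-distance is ≤ 1.
    """
    i = int(rng.integers(theta2.size))
    out = np.array(theta2, dtype=np.int64)
    out[i] = int(rng.choice(_THETA2_VALUES))
    return out


def initial_candidate(base: Genotype, config: ESConfig, rng: np.random.Generator) -> Genotype:
    """Random candidate: ngh weight edits and ngh threshold edits of the base."""
    lo, hi = config.ngh_range
    ngh = int(rng.integers(lo, hi + 1))
    W, t2 = base.W, base.theta2
    for _ in range(ngh):
        W = rule1(W, rng)
    for _ in range(ngh):
        t2 = rule2(t2, rng)
    return Genotype(W, t2)


def _mutate(g: Genotype, rng: np.random.Generator) -> Genotype:
    """One weight edit plus one threshold edit (the per-generation mutation)."""
    return Genotype(rule1(g.W, rng), rule2(g.theta2, rng))


# ---------------------------------------------------------------------------
# fitness

def _target_pairs(target: TargetSequence) -> tuple[np.ndarray, np.ndarray]:
    rows = np.asarray(target.states, dtype=np.int64)
    inputs = rows
    expected = np.vstack([rows[1:], rows[-1:]])  # row 10 must map to itself
    return inputs, expected


def count_mismatches(g: Genotype, target: TargetSequence) -> int:
    """Deviating bits between one-step images of the target rows and the target."""
    inputs, expected = _target_pairs(target)
    if g.W.shape[1] != inputs.shape[1]:
        raise ValueError(
            f"genotype has {g.W.shape[1]} nodes but the target sequence has {inputs.shape[1]}"
        )
    s2 = 2 * inputs @ g.W.T
    th = g.theta2[None, :]
    out = np.where(s2 > th, 1, np.where(s2 < th, 0, inputs))
    return int(np.abs(out - expected).sum())


def fitness(g: Genotype, target: TargetSequence) -> float:
    """Mean absolute deviation over the 10·n target bits; 0 ⇔ functional."""
    n = g.theta2.size
    return count_mismatches(g, target) / (10 * n)


def _evaluate(g: Genotype, target: TargetSequence) -> Candidate:
    return Candidate(g, count_mismatches(g, target), g.theta2.size)


# ---------------------------------------------------------------------------
# the strategy

def _ranked(pop: list[Candidate]) -> list[Candidate]:
    return sorted(pop, key=lambda c: c.mismatches)  # stable: ties keep insertion order


def evolve_generation(
    pop: list[Candidate],
    config: ESConfig,
    base: Genotype,
    rng: np.random.Generator,
    target: TargetSequence,
) -> list[Candidate]:
    """One generation: elites + mutated elites + fresh random candidates."""
    if len(pop) != config.pop_size:
        raise ValueError(f"population size {len(pop)} != configured {config.pop_size}")
    ranked = _ranked(pop)
    elites = ranked[: config.n_elites]
    nxt = list(elites)
    for _ in range(config.n_mutants):
        parent = elites[int(rng.integers(len(elites)))]
        nxt.append(_evaluate(_mutate(parent.genotype, rng), target))
    for _ in range(config.n_mutants):
        nxt.append(_evaluate(initial_candidate(base, config, rng), target))
    return nxt


def run_es(
    config: ESConfig,
    target: TargetSequence,
    base: Genotype,
    rng: np.random.Generator,
    seed_pop: Iterable[Genotype] = (),
) -> tuple[Genotype, int] | None:
    """One ES run: returns (functional genotype, generation found) or None.

    ``seed_pop`` genotypes are placed at the head of generation 0 (a test
    hook; the remainder is filled with random wildtype perturbations).
    """
    pop = [_evaluate(g, target) for g in seed_pop][: config.pop_size]
    while len(pop) < config.pop_size:
        pop.append(_evaluate(initial_candidate(base, config, rng), target))
    for gen in range(config.max_iters + 1):
        winners = [c for c in _ranked(pop) if c.functional]
        if winners:
            return winners[0].genotype, gen
        if gen == config.max_iters:
            return None
        pop = evolve_generation(pop, config, base, rng, target)
    return None


def harvest(
    count: int,
    config: ESConfig | None = None,
    seed: int = 0,
    target: TargetSequence | None = None,
    base: Genotype | None = None,
    progress: Callable[[int, int, int | None], None] | None = None,
) -> list[Genotype]:
    """Collect ``count`` distinct functional genotypes (wildtype included).

    Each ES run contributes at most one network (a restart strategy, so no
    single run's neighbourhood is over-represented).  Run ``k`` draws its RNG
    from ``SeedSequence(seed).spawn``-style child ``(seed, spawn_key=(k,))``,
    so a harvest is fully reproducible from the root seed, and runs are
    independent streams.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    config = config or ESConfig()
    target = target or cell_cycle_sequence()
    if base is None:
        base = Genotype.of(wildtype())
    found: dict[bytes, Genotype] = {base.key(): base}
    run_id = 0
    while len(found) < count:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(run_id,)))
        res = run_es(config, target, base, rng)
        if res is not None:
            g, gen = res
            if g.key() not in found:
                found[g.key()] = g
            if progress:
                progress(run_id, len(found), gen)
            log.info("run %d: functional network at generation %d (have %d)", run_id, gen, len(found))
        else:
            if progress:
                progress(run_id, len(found), None)
            log.info("run %d: no functional network within %d generations", run_id, config.max_iters)
        run_id += 1
    return list(found.values())
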