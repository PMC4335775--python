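"""Downstream analyses of a harvested neutral graph.

Three families of questions about the functional networks:

* topology — how many edges (nonzero weights) do they carry, split into
  activating (positive) and inhibiting (negative), and how does the
  distribution differ between the wildtype connected component and the rest;
* edge conservation — which individual interactions (e.g. the positive edge
  activating Slp1) are present in what fraction of each group;
* state space — how large is the basin of attraction of the G1 fixed point
  under each updating scheme, again by group.  The group comparison is
  descriptive (summaries and fixed-bin histograms); a two-sample
  Kolmogorov–Smirnov statistic is available as an optional add-on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evolution import Genotype
from .fission_yeast import NODE_LABELS, g1_index
from .network import (
    UpdateScheme,
    build_transition_graph,
    estimate_async_basin,
    find_attractors,
    fixed_points_mask,
)
from .neutral import NeutralGraph, wildtype_component

__all__ = [
    "CANONICAL_BLOCKS",
    "CANONICAL_ORDER",
    "default_scheme",
    "edge_counts",
    "edge_frequencies",
    "activator_frequency",
    "g1_basin_measure",
    "basin_by_group",
    "histogram_report",
]

#: Block partition used for the block-sequential analyses:
#: (Start, SK, Cdc2/Cdc13)(Ste9, Rum1, Slp1, Cdc2/Cdc13*)(Wee1/Mik1, Cdc25, PP).
CANONICAL_BLOCKS: tuple[tuple[int, ...], ...] = ((0, 1, 2), (3, 4, 5, 6), (7, 8, 9))

#: Node order used for the sequential analyses (the table column order).
CANONICAL_ORDER: tuple[int, ...] = tuple(range(10))


def default_scheme(mode: str) -> UpdateScheme:
    """The updating scheme with the canonical order/blocks for this model."""
    if mode == "block_sequential":
        return UpdateScheme(mode, blocks=CANONICAL_BLOCKS)
    if mode in ("sequential", "async_deterministic"):
        return UpdateScheme(mode, order=CANONICAL_ORDER)
    return UpdateScheme(mode)


# ---------------------------------------------------------------------------
# topology

def edge_counts(g: Genotype) -> tuple[int, int, int]:
    """(total, positive, negative) nonzero weight entries, diagonal included."""
    pos = int((g.W > 0).sum())
    neg = int((g.W < 0).sum())
    return pos + neg, pos, neg


def edge_frequencies(group: list[Genotype]) -> dict[str, np.ndarray]:
    """Per-position presence frequencies over a group of genotypes.

    Returns n×n arrays ``present`` (fraction with W[i,j] ≠ 0), ``positive``
    and ``negative``.
    """
    if not group:
        raise ValueError("edge_frequencies needs a nonempty group")
    stack = np.stack([g.W for g in group])
    return {
        "present": (stack != 0).mean(axis=0),
        "positive": (stack > 0).mean(axis=0),
        "negative": (stack < 0).mean(axis=0),
    }


def activator_frequency(group: list[Genotype], node: int | str) -> float:
    """Fraction of the group with at least one positive inbound edge to ``node``."""
    if isinstance(node, str):
        node = NODE_LABELS.index(node)
    if not group:
        raise ValueError("activator_frequency needs a nonempty group")
    return float(np.mean([(g.W[node] > 0).any() for g in group]))


# ---------------------------------------------------------------------------
# basins of attraction

def g1_basin_measure(
    g: Genotype,
    scheme: UpdateScheme,
    runs: int = 20,
    max_steps: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Basin measure of the G1 fixed point for one genotype.

    Deterministic schemes: exact basin size (an integer in [1, 2ⁿ]) from the
    full transition graph.  Fully asynchronous: Monte-Carlo expected basin
    mass.  A genotype for which G1 is not a fixed point gets measure 0
    (cannot happen for functional networks — the G1 self-transition is part
    of the target).
    """
    net = g.to_network(NODE_LABELS)
    g1 = g1_index()
    if scheme.mode == "fully_async":
        if not fixed_points_mask(net)[g1]:
            return 0.0
        _, mass = estimate_async_basin(net, g1, runs=runs, max_steps=max_steps, seed=seed)
        return mass
    tg = build_transition_graph(net, scheme)
    if int(tg.successor[g1]) != g1:
        return 0.0
    att = find_attractors(tg)
    aid = int(att.attractor_of[g1])
    return float((att.attractor_of == aid).sum())


def basin_by_group(
    ng: NeutralGraph,
    scheme: UpdateScheme,
    runs: int = 20,
    max_steps: int | None = None,
    seed: int = 0,
    ks_test: bool = False,
):
    """G1 basin measures for every genotype, grouped by component membership.

    Returns ``(per_genotype, summary)`` DataFrames; with ``ks_test=True`` the
    summary gains a two-sample Kolmogorov–Smirnov statistic comparing the two
    groups (a descriptive add-on, reported alongside medians and IQRs).
    For the fully asynchronous scheme genotype ``i`` uses the child stream
    ``(seed, spawn_key=(i,))`` so the whole table is seed-reproducible.
    """
    comp = wildtype_component(ng)
    rows = []
    for i, g in enumerate(ng.genotypes):
        if scheme.mode == "fully_async":
            s = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
            measure = g1_basin_measure(g, scheme, runs=runs, max_steps=max_steps, seed=s)
        else:
            measure = g1_basin_measure(g, scheme)
        rows.append(
            {
                "node": i,
                "group": "component" if i in comp else "rest",
                "basin": measure,
                "flagged_no_g1": measure == 0.0,
            }
        )
    per_genotype = pd.DataFrame(rows)
    summary = (
        per_genotype.groupby("group")["basin"]
        .agg(
            count="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            min="min",
            max="max",
        )
        .reset_index()
    )
    if ks_test and per_genotype["group"].nunique() == 2:
        from scipy.stats import ks_2samp

        a = per_genotype.loc[per_genotype.group == "component", "basin"]
        b = per_genotype.loc[per_genotype.group == "rest", "basin"]
        res = ks_2samp(a, b)
        summary.attrs["ks_statistic"] = float(res.statistic)
        summary.attrs["ks_pvalue"] = float(res.pvalue)
    return per_genotype, summary


# ---------------------------------------------------------------------------
# reports

def histogram_report(ng: NeutralGraph) -> pd.DataFrame:
    """Edge-count histograms for all / component / rest × total / positive / negative.

    Unit-width integer bins over [0, n²]; long-format table with columns
    (group, kind, bin, count).  Within each (group, kind) panel the counts
    sum to the group size.
    """
    comp = wildtype_component(ng)
    counts = {i: edge_counts(g) for i, g in enumerate(ng.genotypes)}
    n2 = ng.genotypes[0].W.size
    groups = {
        "all": list(counts),
        "component": [i for i in counts if i in comp],
        "rest": [i for i in counts if i not in comp],
    }
    kinds = {"total": 0, "positive": 1, "negative": 2}
    rows = []
    for gname, members in groups.items():
        for kname, k in kinds.items():
            vals = [counts[i][k] for i in members]
            hist = np.bincount(vals, minlength=n2 + 1) if vals else np.zeros(n2 + 1, int)
            for b, c in enumerate(hist):
                rows.append({"group": gname, "kind": kname, "bin": b, "count": int(c)})
    return pd.DataFrame(rows)


def basin_histogram(per_genotype: pd.DataFrame, n_states: int = 1024, bins: int = 20) -> pd.DataFrame:
    """Fixed-bin histogram of basin measures per group (20 equal bins over [0, 2ⁿ])."""
    edges = np.linspace(0, n_states, bins + 1)
    rows = []
    for gname, sub in per_genotype.groupby("group"):
        hist, _ = np.histogram(sub["basin"], bins=edges)
        for b in range(bins):
            rows.append(
                {
                    "group": gname,
                    "bin_left": float(edges[b]),
                    "bin_right": float(edges[b + 1]),
                    "count": int(hist[b]),
                }
            )
    return pd.DataFrame(rows)
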