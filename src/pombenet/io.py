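"""Serialization and run plumbing: network JSON, harvest JSONL, report TSV,
ES config YAML and the run manifest.

All randomness in a pipeline flows from a single root seed recorded in the
manifest; rerunning with the same seed reproduces every artifact byte for
byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Iterable

import yaml

from .evolution import ESConfig, Genotype
from .fission_yeast import NODE_LABELS
from .network import ThresholdNetwork, TransitionGraph, find_attractors, index_to_state

__all__ = [
    "load_network",
    "save_network",
    "save_collection",
    "load_collection",
    "load_es_config",
    "export_transition_graph",
    "write_manifest",
]


def _theta_out(net: ThresholdNetwork) -> list:
    return [int(t) if t.denominator == 1 else float(t) for t in net.theta]


def load_network(path) -> ThresholdNetwork:
    """Read a network JSON file ({labels, W, theta}); enforces value sets."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"{path}: malformed JSON ({e})") from e
    for field in ("labels", "W", "theta"):
        if field not in raw:
            raise ValueError(f"{path}: missing required field '{field}'")
    try:
        return ThresholdNetwork.from_theta(raw["labels"], raw["W"], raw["theta"])
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def save_network(net: ThresholdNetwork, path) -> None:
    payload = {"labels": list(net.labels), "W": net.W.tolist(), "theta": _theta_out(net)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def save_collection(genotypes: Iterable[Genotype], path, labels=NODE_LABELS, meta=None) -> None:
    """One network per JSONL line (streams without loading everything)."""
    meta = meta or {}
    with open(path, "w") as fh:
        for i, g in enumerate(genotypes):
            net = g.to_network(tuple(labels))
            rec = {
                "id": i,
                "labels": list(labels),
                "W": g.W.tolist(),
                "theta": _theta_out(net),
            }
            if i in meta:
                rec.update(meta[i])
            fh.write(json.dumps(rec) + "\n")


def load_collection(path) -> list[Genotype]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            raw = json.loads(line)
            net = ThresholdNetwork.from_theta(raw["labels"], raw["W"], raw["theta"])
            out.append(Genotype.of(net))
    return out


def load_es_config(path) -> ESConfig:
    """ES parameters from YAML (keys mirror ESConfig fields; all optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"pop_size", "elite_frac", "max_iters", "ngh_range"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config field(s) {sorted(unknown)}")
    if "ngh_range" in raw:
        raw["ngh_range"] = tuple(raw["ngh_range"])
    return ESConfig(**raw)


def export_transition_graph(tg: TransitionGraph, path) -> None:
    """TSV: state_index, state_bits, successor_index, attractor_id, attractor_type."""
    att = find_attractors(tg)
    types = ["fixed_point" if len(a) == 1 else "limit_cycle" for a in att.attractors]
    with open(path, "w") as fh:
        fh.write("state_index\tstate_bits\tsuccessor_index\tattractor_id\tattractor_type\n")
        for s in range(tg.n_states):
            bits = "".join(str(b) for b in index_to_state(s, tg.n))
            aid = int(att.attractor_of[s])
            fh.write(f"{s}\t{bits}\t{int(tg.successor[s])}\t{aid}\t{types[aid]}\n")


def write_manifest(path, *, seed: int, config: ESConfig, counts: dict, extra=None) -> None:
    import pombenet

    payload = {
        "version": pombenet.__version__,
        "seed": seed,
        "es_config": asdict(config),
        "counts": counts,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
        fh.write("\n")
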