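"""Synthetic heterogeneous networks with a planted interaction rule.

The generator emulates the structure of a four-type biomedical network
(drugs, proteins, diseases, side-effects) at desk scale.  Background
relations are independent Bernoulli edge sets; the drug-protein positives
are *planted*: a pair interacts exactly when a chosen relation-type path
connects it (by default the two-hop ``drug -> disease -> protein`` rule,
i.e. the pair shares at least one associated disease).  An optional noise
fraction deletes true positives and promotes random unconnected pairs,
simulating incomplete and mislabeled interaction catalogs.

Because the generative rule is known, a search over this network has a
ground truth: a recovered meta-graph should route information through the
planted relation types, and ``recovery_rate`` measures how often it does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
import json

import numpy as np

from .hetnet import HetNet, NodeCatalog, save_hetnet, transpose_name
from .metagraph import MetaGraph

__all__ = [
    "PlantedSpec",
    "PlantedNetwork",
    "generate_planted_hetnet",
    "recovery_rate",
    "save_planted_network",
]

DEFAULT_COUNTS = {"drug": 50, "protein": 30, "disease": 15, "side-effect": 20}

DEFAULT_DENSITIES = {
    "drug_drug": 0.02,
    "protein_protein": 0.02,
    "drug_side-effect": 0.03,
    "drug_disease": 0.06,
    "disease_protein": 0.06,
}

DEFAULT_RULE = ("drug_disease", "disease_protein")


@dataclass(frozen=True)
class PlantedSpec:
    """Generator parameters: node counts, edge densities, planted rule, noise."""

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    densities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    rule: tuple[str, ...] = DEFAULT_RULE
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise must lie in [0, 0.5)")
        for name, dens in self.densities.items():
            if not (0.0 <= dens <= 1.0):
                raise ValueError(f"density of {name!r} outside [0, 1]")
        types = [self._rel_types(r) for r in self.rule]
        if types[0][0] != "drug" or types[-1][1] != "protein":
            raise ValueError("planted rule must run from drug to protein")
        for (a, b) in zip(types, types[1:]):
            if a[1] != b[0]:
                raise ValueError("planted rule path types do not chain")
        for t in {t for pair in types for t in pair}:
            if self.counts.get(t, 0) <= 0:
                raise ValueError(f"rule references node type {t!r} with zero count")

    @staticmethod
    def _rel_types(name: str) -> tuple[str, str]:
        src, _, dst = name.partition("_")
        return src, dst


@dataclass
class PlantedNetwork:
    """Generated network plus its ground-truth interaction pairs."""

    net: HetNet
    positives: set[tuple[int, int]]
    planted_relations: tuple[str, ...]
    spec: PlantedSpec

    @property
    def drug_indices(self) -> np.ndarray:
        return self.net.catalog.indices_of_type("drug")

    @property
    def protein_indices(self) -> np.ndarray:
        return self.net.catalog.indices_of_type("protein")


def _bernoulli_edges(
    rows: np.ndarray, cols: np.ndarray, density: float, rng: np.random.Generator,
    exclude_diagonal: bool,
) -> set[tuple[int, int]]:
    mask = rng.random((rows.size, cols.size)) < density
    edges = set()
    for a, b in zip(*np.nonzero(mask)):
        u, v = int(rows[a]), int(cols[b])
        if exclude_diagonal and u == v:
            continue
        edges.add((u, v))
    return edges


def _path_connected_pairs(
    net: HetNet, rule: tuple[str, ...]
) -> set[tuple[int, int]]:
    """All (drug, protein) pairs joined by the planted relation path."""
    frontier: dict[int, set[int]] = {
        d: {d} for d in net.catalog.indices_of_type("drug")
    }
    for rel in rule:
        succ: dict[int, set[int]] = {}
        for u, v in net.relations[rel]:
            succ.setdefault(u, set()).add(v)
        frontier = {
            d: {v for node in reach for v in succ.get(node, ())}
            for d, reach in frontier.items()
        }
    return {(d, p) for d, reach in frontier.items() for p in reach}


def generate_planted_hetnet(spec: PlantedSpec) -> PlantedNetwork:
    """Sample a planted network; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for node_type, count in sorted(spec.counts.items()):
        width = len(str(max(1, count - 1)))
        for k in range(count):
            pairs.append((f"{node_type}-{k:0{width}d}", node_type))
    catalog = NodeCatalog.from_pairs(pairs)

    relations: dict[str, set[tuple[int, int]]] = {}
    typing: dict[str, tuple[str, str]] = {}
    for name in sorted(spec.densities):
        src_t, dst_t = PlantedSpec._rel_types(name)
        rows = catalog.indices_of_type(src_t)
        cols = catalog.indices_of_type(dst_t)
        relations[name] = _bernoulli_edges(
            rows, cols, spec.densities[name], rng, exclude_diagonal=src_t == dst_t
        )
        typing[name] = (src_t, dst_t)
    net = HetNet.from_edges(catalog, relations, typing)

    positives = _path_connected_pairs(net, spec.rule)
    if spec.noise > 0.0:
        pos_sorted = sorted(positives)
        n_flip = int(round(spec.noise * len(pos_sorted)))
        drop = rng.choice(len(pos_sorted), size=n_flip, replace=False)
        dropped = {pos_sorted[k] for k in drop}
        drugs = catalog.indices_of_type("drug")
        prots = catalog.indices_of_type("protein")
        non_pairs = sorted(
            set(product(map(int, drugs), map(int, prots))) - positives
        )
        add = rng.choice(len(non_pairs), size=min(n_flip, len(non_pairs)),
                         replace=False)
        positives = (positives - dropped) | {non_pairs[k] for k in add}
    if not positives:
        raise ValueError("planted rule produced no positive pairs; raise densities")
    if len(positives) < 20:
        import warnings

        warnings.warn(
            f"only {len(positives)} planted positives; statistics will be noisy"
        )
    return PlantedNetwork(
        net=net,
        positives=positives,
        planted_relations=tuple(spec.rule),
        spec=spec,
    )


def recovery_rate(
    found: list[MetaGraph], planted_relations: tuple[str, ...]
) -> float:
    """Fraction of meta-graphs whose slots include a planted relation.

    A planted relation counts in either orientation, since its transpose
    carries the same information.
    """
    if not found:
        raise ValueError("need at least one meta-graph")
    wanted = set(planted_relations) | {
        transpose_name(r) for r in planted_relations
    }
    hits = sum(
        1 for mg in found if set(mg.real_slots().values()) & wanted
    )
    return hits / len(found)


def save_planted_network(planted: PlantedNetwork, out_dir: str | Path) -> Path:
    """Write TSV/manifest fixture files plus ground-truth positives."""
    out_dir = Path(out_dir)
    manifest = save_hetnet(planted.net, out_dir)
    ids = planted.net.catalog.ids
    with open(out_dir / "positives.tsv", "w") as fh:
        for d, p in sorted(planted.positives):
            fh.write(f"{ids[d]}\t{ids[p]}\n")
    echo = {
        "counts": planted.spec.counts,
        "densities": planted.spec.densities,
        "rule": list(planted.spec.rule),
        "noise": planted.spec.noise,
        "seed": planted.spec.seed,
        "planted_relations": list(planted.planted_relations),
    }
    with open(out_dir / "planted_spec.json", "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)
    return manifest
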