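"""Splitting, ranking metrics and meta-graph frequency analysis.

Positives and sampled negatives are partitioned per class into 60/20/20
train/validation/test sets, independently re-drawn for each repeat.  Test
performance is summarized by AUROC and AUPRC (average precision).  The
frequency table tallies how often each propagation mode is selected across
a collection of searched meta-graphs, one count per slot.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .metagraph import IDENTITY, NULL, MetaGraph
from .training import InteractionSets, PairScore

__all__ = [
    "SplitSet",
    "MetricsReport",
    "FrequencyTable",
    "make_splits",
    "compute_metrics",
    "edge_type_frequency",
]


@dataclass(frozen=True)
class SplitSet:
    """One train/validation/test partition of the positive/negative pools."""

    train: InteractionSets
    validation: InteractionSets
    test: InteractionSets
    fractions: tuple[float, float, float]
    repeat: int
    seed: int


@dataclass(frozen=True)
class MetricsReport:
    """Test-set ranking quality for one evaluation."""

    auc: float
    auprc: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auprc": self.auprc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _partition(
    pool: Iterable[tuple[int, int]],
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[list, list, list]:
    items = sorted(pool)
    order = rng.permutation(len(items))
    n = len(items)
    n_tr = int(round(fractions[0] * n))
    n_va = int(round(fractions[1] * n))
    idx_tr = order[:n_tr]
    idx_va = order[n_tr: n_tr + n_va]
    idx_te = order[n_tr + n_va:]
    return (
        [items[k] for k in idx_tr],
        [items[k] for k in idx_va],
        [items[k] for k in idx_te],
    )


def make_splits(
    positives: set[tuple[int, int]],
    negatives: set[tuple[int, int]],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    repeats: int = 1,
    seed: int = 0,
) -> list[SplitSet]:
    """Stratified random train/validation/test partitions, one per repeat."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if set(positives) & set(negatives):
        raise ValueError("positive and negative pools overlap")
    splits: list[SplitSet] = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        pos_parts = _partition(positives, fractions, rng)
        neg_parts = _partition(negatives, fractions, rng)
        if any(len(p) == 0 for p in pos_parts):
            raise ValueError("a split received zero positives; pool too small")
        ratio = max(1, len(negatives) // max(1, len(positives)))
        parts = [
            InteractionSets(
                positives=frozenset(p), negatives=frozenset(n), ratio=ratio
            )
            for p, n in zip(pos_parts, neg_parts)
        ]
        splits.append(
            SplitSet(
                train=parts[0],
                validation=parts[1],
                test=parts[2],
                fractions=tuple(fractions),
                repeat=rep,
                seed=seed,
            )
        )
    return splits


def compute_metrics(
    scores: Sequence[PairScore],
    labels: Mapping[tuple[int, int], int],
) -> MetricsReport:
    """AUROC (rank-based, ties get half credit) and AUPRC (average precision)."""
    y_true = []
    y_score = []
    for ps in scores:
        key = (ps.drug, ps.protein)
        if key not in labels:
            raise ValueError(f"no label for pair {key}")
        y_true.append(labels[key])
        y_score.append(ps.score)
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    n_pos = int(y_true.sum())
    n_neg = int(len(y_true) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics require both classes present")
    return MetricsReport(
        auc=float(roc_auc_score(y_true, y_score)),
        auprc=float(average_precision_score(y_true, y_score)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


@dataclass(frozen=True)
class FrequencyTable:
    """Selected-mode counts across a collection of meta-graphs."""

    counts: dict[str, int]
    total_metagraphs: int

    def most_common(self, k: int | None = None, real_only: bool = True) -> list[tuple[str, int]]:
        items = [
            (name, c)
            for name, c in self.counts.items()
            if not (real_only and name in (IDENTITY, NULL))
        ]
        items.sort(key=lambda kv: (-kv[1], kv[0]))
        return items if k is None else items[:k]

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{name}\t{c}\n")


def edge_type_frequency(metagraphs: Sequence[MetaGraph]) -> FrequencyTable:
    """Tally each selected mode once per slot across all meta-graphs."""
    if not metagraphs:
        raise ValueError("need at least one meta-graph")
    counter: Counter[str] = Counter()
    for mg in metagraphs:
        counter.update(mg.selected.values())
    return FrequencyTable(counts=dict(counter), total_metagraphs=len(metagraphs))
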