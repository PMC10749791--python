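"""Model/Results interface tying the whole pipeline together.

:class:`AdaptiveMetaGraphDTI` is constructed from a heterogeneous network
and a set of known drug-protein interactions; :meth:`fit` runs the full
procedure -- node2vec encoding, negative under-sampling, 60/20/20
splitting, per-role bilevel meta-graph search, final retraining and
test-set evaluation -- and returns a :class:`DTIResults` carrying the
searched meta-graphs, trained weights, per-repeat metrics and a
``summary()`` table.  Ranked predictions for unknown pairs hang off the
results object.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .embedding import EmbeddingMatrix, node2vec_embeddings, one_hot_embeddings
from .evaluation import MetricsReport, SplitSet, compute_metrics, make_splits
from .hetnet import HetNet, NormalizedRelation, load_hetnet_from_manifest, normalized_relations
from .metagraph import MetaGraph, RelationCatalog, SignificanceTensor
from .training import (
    InteractionSets,
    PairScore,
    TrainConfig,
    TrainedModel,
    predict_ranked,
    sample_negatives,
    search_metagraph,
    train_final,
)

__all__ = ["AdaptiveMetaGraphDTI", "DTIResults", "derive_seed"]


def derive_seed(seed: int, *tags: object) -> int:
    """Stable per-stage seed below 2**31 derived from a global seed."""
    h = zlib.crc32(("|".join(str(t) for t in tags)).encode())
    return (int(seed) * 1_000_003 + h) % (2**31 - 1)


@dataclass
class RepeatResult:
    """Everything produced by one resampling repeat."""

    split: SplitSet
    metagraph_drug: MetaGraph
    metagraph_protein: MetaGraph
    sig_drug: SignificanceTensor
    sig_protein: SignificanceTensor
    model: TrainedModel
    metrics: MetricsReport


class AdaptiveMetaGraphDTI:
    """Drug-target interaction model over a heterogeneous network.

    Parameters
    ----------
    net
        The heterogeneous network (drugs, proteins and context types).
    positives
        Known drug-protein interaction pairs as global node indices.
    config
        Optimization hyperparameters; defaults follow the standard recipe
        (Adam, learning rate 6e-3, weight decay 1e-3, hidden size 64,
        one-shot learning-rate decay 0.2, 150 epochs, T = 3).
    embedding
        Optional precomputed ``H^0``; when omitted, node2vec features are
        trained during :meth:`fit` (``encoder="one-hot"`` selects the
        identity-encoding ablation instead).
    """

    def __init__(
        self,
        net: HetNet,
        positives: set[tuple[int, int]],
        config: TrainConfig | None = None,
        embedding: EmbeddingMatrix | None = None,
        encoder: str = "node2vec",
    ):
        if not positives:
            raise ValueError("need at least one known interaction")
        self.net = net
        self.positives = set(positives)
        self.config = config or TrainConfig()
        self.embedding = embedding
        self.encoder = encoder
        self.relations: Mapping[str, NormalizedRelation] = normalized_relations(net)
        self.catalog = RelationCatalog.from_hetnet(net)
        self.drugs = [int(i) for i in net.catalog.indices_of_type("drug")]
        self.proteins = [int(i) for i in net.catalog.indices_of_type("protein")]
        if not self.drugs or not self.proteins:
            raise ValueError("network must contain drug and protein nodes")

    @classmethod
    def from_files(
        cls,
        manifest_path: str | Path,
        positives_path: str | Path,
        **kwargs,
    ) -> "AdaptiveMetaGraphDTI":
        """Build from a network manifest and a two-column positives TSV."""
        net = load_hetnet_from_manifest(manifest_path)
        positives: set[tuple[int, int]] = set()
        with open(positives_path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                d_id, p_id = line.split("\t")
                positives.add((net.catalog.index[d_id], net.catalog.index[p_id]))
        return cls(net, positives, **kwargs)

    # -- fitting ------------------------------------------------------

    def encode(self, seed: int) -> EmbeddingMatrix:
        """Compute (or return the cached) ``H^0`` node features."""
        if self.embedding is not None:
            return self.embedding
        if self.encoder == "one-hot":
            self.embedding = one_hot_embeddings(self.net)
        else:
            self.embedding = node2vec_embeddings(
                self.net,
                d=self.config.hidden_size,
                seed=derive_seed(seed, "embed"),
            )
        return self.embedding

    def fit(self, seed: int = 0, repeats: int = 1) -> "DTIResults":
        """Run the full search/train/evaluate pipeline.

        Negatives are sampled once (``config.ratio`` per positive), then
        each repeat re-partitions both pools 60/20/20, searches one
        meta-graph per role, retrains fresh weights on the fixed
        meta-graphs and evaluates on held-out pairs.
        """
        cfg = self.config
        H0 = self.encode(seed).H
        neg_rng = np.random.default_rng(derive_seed(seed, "negatives"))
        pools = sample_negatives(
            self.positives, self.drugs, self.proteins, cfg.ratio, neg_rng
        )
        splits = make_splits(
            set(pools.positives),
            set(pools.negatives),
            repeats=repeats,
            seed=derive_seed(seed, "splits"),
        )
        results: list[RepeatResult] = []
        for split in splits:
            tag = split.repeat
            mg_d, sig_d = search_metagraph(
                self.net, H0, split.train, split.validation, "drug",
                cfg.with_seed(derive_seed(seed, "search", "drug", tag)),
                relations=self.relations, catalog=self.catalog,
            )
            mg_p, sig_p = search_metagraph(
                self.net, H0, split.train, split.validation, "protein",
                cfg.with_seed(derive_seed(seed, "search", "protein", tag)),
                relations=self.relations, catalog=self.catalog,
            )
            model = train_final(
                self.net, H0, mg_d, mg_p, split.train,
                cfg.with_seed(derive_seed(seed, "final", tag)),
                relations=self.relations,
                val_sets=split.validation,
            )
            scores = self._score_sets(model, split.test)
            labels = {(d, p): 1 for d, p in split.test.positives}
            labels.update({(d, p): 0 for d, p in split.test.negatives})
            metrics = compute_metrics(scores, labels)
            results.append(
                RepeatResult(
                    split=split,
                    metagraph_drug=mg_d,
                    metagraph_protein=mg_p,
                    sig_drug=sig_d,
                    sig_protein=sig_p,
                    model=model,
                    metrics=metrics,
                )
            )
        return DTIResults(model=self, seed=seed, repeats=results)

    def _score_sets(
        self, model: TrainedModel, sets: InteractionSets
    ) -> list[PairScore]:
        pairs = set(sets.positives) | set(sets.negatives)
        return predict_ranked(model, self.relations, pairs, top_k=None)


@dataclass
class DTIResults:
    """Fit output: searched meta-graphs, trained weights and metrics."""

    model: AdaptiveMetaGraphDTI
    seed: int
    repeats: list[RepeatResult] = field(default_factory=list)

    # -- aggregate metrics --------------------------------------------

    @property
    def best(self) -> RepeatResult:
        """Repeat with the highest test AUROC (the headline convention)."""
        return max(self.repeats, key=lambda r: r.metrics.auc)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.metrics.auc for r in self.repeats]))

    @property
    def mean_auprc(self) -> float:
        return float(np.mean([r.metrics.auprc for r in self.repeats]))

    # -- prediction ---------------------------------------------------

    def predict_ranked(
        self, top_k: int | None = 10, exclude: set[tuple[int, int]] | None = None
    ) -> list[PairScore]:
        """Rank unknown drug-protein pairs by interaction probability.

        All known positives (and any extra ``exclude`` pairs) are removed
        from the candidate set; scoring uses the best repeat's model.
        """
        m = self.model
        known = set(m.positives) | (exclude or set())
        candidates = {
            (d, p) for d in m.drugs for p in m.proteins if (d, p) not in known
        }
        return predict_ranked(self.best.model, m.relations, candidates, top_k=top_k)

    def prediction_table(self, top_k: int = 10) -> list[tuple[str, str, float]]:
        """Ranked predictions with node ids instead of indices."""
        ids = self.model.net.catalog.ids
        return [
            (ids[s.drug], ids[s.protein], s.score)
            for s in self.predict_ranked(top_k=top_k)
        ]

    # -- reporting ----------------------------------------------------

    def summary(self) -> str:
        """Plain-text fit report."""
        m = self.model
        lines = [
            "Adaptive Meta-Graph DTI Results",
            "=" * 46,
            f"nodes: {m.net.n_nodes}   drugs: {len(m.drugs)}   proteins: {len(m.proteins)}",
            f"relations: {len(m.net.relation_names())}   positives: {len(m.positives)}"
            f"   neg ratio: 1:{m.config.ratio}",
            f"T = {m.config.T}   hidden = {m.config.hidden_size}   "
            f"epochs = {m.config.epochs}   seed = {self.seed}",
            "-" * 46,
            f"{'repeat':>6} {'AUROC':>8} {'AUPRC':>8} {'n_test+':>8} {'n_test-':>8}",
        ]
        for r in self.repeats:
            lines.append(
                f"{r.split.repeat:>6} {r.metrics.auc:>8.4f} {r.metrics.auprc:>8.4f}"
                f" {r.metrics.n_pos:>8} {r.metrics.n_neg:>8}"
            )
        lines += [
            "-" * 46,
            f"mean AUROC {self.mean_auc:.4f}   mean AUPRC {self.mean_auprc:.4f}",
            f"best AUROC {self.best.metrics.auc:.4f}   "
            f"best AUPRC {self.best.metrics.auprc:.4f}",
            "drug meta-graph:    "
            + ", ".join(
                f"({i},{t})={mode}"
                for (i, t), mode in sorted(self.best.metagraph_drug.selected.items(),
                                           key=lambda kv: (kv[0][1], kv[0][0]))
            ),
            "protein meta-graph: "
            + ", ".join(
                f"({i},{t})={mode}"
                for (i, t), mode in sorted(self.best.metagraph_protein.selected.items(),
                                           key=lambda kv: (kv[0][1], kv[0][0]))
            ),
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write meta-graph JSONs, metrics JSON and the prediction TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        best = self.best
        best.metagraph_drug.save(out_dir / "metagraph_drug.json")
        best.metagraph_protein.save(out_dir / "metagraph_protein.json")
        best.metrics.save(out_dir / "metrics.json")
        ids = self.model.net.catalog.ids
        with open(out_dir / "predictions.tsv", "w") as fh:
            for s in self.predict_ranked(top_k=10):
                fh.write(f"{ids[s.drug]}\t{ids[s.protein]}\t{s.score:.6f}\n")
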