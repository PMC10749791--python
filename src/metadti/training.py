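"""Bilevel meta-graph search, final training and pair scoring.

The search optimizes two coupled parameter sets: the GCN weight matrices
``omega`` (one per slot) and the architecture significances ``alpha`` (one
vector per slot).  Each search step samples a concrete architecture --
argmax of the softmax significances with a linearly decaying uniform
exploration probability -- and takes one Adam step on ``omega`` against
the training loss of that sampled plan; the significances then take one
Adam step against the validation loss of the theta-weighted supernet in
which every slot mixes all of its candidates.  This first-order
alternation approximates the bilevel program

    min_alpha  L_val(omega*(alpha), alpha)
    s.t.       omega*(alpha) = argmin_omega L_tra(omega, alpha).

A short warm-up (``warmup_frac`` of the steps) trains the weights on
uniformly sampled architectures before any significance update, so early
architecture gradients compare candidates whose weights have all seen
some training.

The link loss is the logsigmoid ranking loss over known interactions
(positives) and sampled non-interactions (negatives):

    L = - sum_{(d,p) in pos} log sigma(h_d . h_p)
        - sum_{(d,p) in neg} log sigma(-h_d . h_p).

After the search, the argmax meta-graphs are fixed and the weights are
re-initialized and trained on the same loss (search-then-retrain).  A
drug-protein pair is finally scored as ``sigmoid(h_d . h_p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .hetnet import HetNet, NormalizedRelation, normalized_relations
from .metagraph import (
    MetaGraph,
    RelationCatalog,
    SignificanceTensor,
    all_slots,
    derive_final_metagraph,
    exploration_probability,
    select_relation,
)
from .propagation import (
    PropagationWeights,
    backward,
    forward_cached,
    mixture_backward_alpha,
    mixture_forward,
)

__all__ = [
    "InteractionSets",
    "TrainConfig",
    "TrainedModel",
    "PairScore",
    "sample_negatives",
    "score_pair",
    "dti_loss",
    "dti_loss_grad",
    "search_metagraph",
    "train_final",
    "predict_ranked",
]


@dataclass(frozen=True)
class InteractionSets:
    """Positive and sampled negative drug-protein pairs (global indices)."""

    positives: frozenset[tuple[int, int]]
    negatives: frozenset[tuple[int, int]]
    ratio: int = 1

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positive and negative pairs overlap")

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults as used throughout).

    ``lr_decay`` is a one-shot learning-rate multiplier applied at the
    epoch midpoint; ``p0`` the initial exploration probability of the
    architecture sampler.  The architecture significances take larger Adam
    steps (``alpha_learning_rate``) than the weights: they start from a
    uniform random initialization whose spread would otherwise dominate
    the ~100 post-warm-up updates of a search.
    """

    learning_rate: float = 6e-3
    alpha_learning_rate: float = 0.02
    weight_decay: float = 1e-3
    hidden_size: int = 64
    lr_decay: float = 0.2
    epochs: int = 150
    T: int = 3
    ratio: int = 1
    p0: float = 0.1
    warmup_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.weight_decay, self.lr_decay) <= 0:
            raise ValueError("rates must be positive")
        if min(self.hidden_size, self.epochs, self.T, self.ratio) <= 0:
            raise ValueError("sizes must be positive")

    def with_seed(self, seed: int) -> "TrainConfig":
        return replace(self, seed=seed)


@dataclass
class TrainedModel:
    """Final meta-graphs with their trained GCN weights and input features."""

    metagraph_drug: MetaGraph
    metagraph_protein: MetaGraph
    weights_drug: PropagationWeights
    weights_protein: PropagationWeights
    H0: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def features(
        self, relations: Mapping[str, NormalizedRelation]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Propagated final states: (drug-side H^T, protein-side H^T)."""
        seq_d, _ = forward_cached(
            self.H0, self.metagraph_drug.selected, self.weights_drug, relations
        )
        seq_p, _ = forward_cached(
            self.H0, self.metagraph_protein.selected, self.weights_protein, relations
        )
        return seq_d.final, seq_p.final


@dataclass(frozen=True)
class PairScore:
    """One scored drug-protein pair."""

    drug: int
    protein: int
    score: float


# ---------------------------------------------------------------------------
# Sampling and loss
# ---------------------------------------------------------------------------


def sample_negatives(
    known_positives: set[tuple[int, int]],
    all_drugs: Sequence[int],
    all_proteins: Sequence[int],
    ratio: int,
    rng: np.random.Generator,
) -> InteractionSets:
    """Uniformly under-sample unknown pairs as presumed non-interactions.

    Draws ``ratio * |positives|`` distinct drug-protein pairs, without
    replacement, from the pairs absent from ``known_positives``.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    drugs = np.asarray(sorted(all_drugs))
    prots = np.asarray(sorted(all_proteins))
    n_all = drugs.size * prots.size
    needed = ratio * len(known_positives)
    n_unknown = n_all - len(known_positives)
    if needed > n_unknown:
        raise ValueError(
            f"cannot sample {needed} negatives: only {n_unknown} unknown pairs exist"
        )
    pos_flat = {
        int(np.searchsorted(drugs, d)) * prots.size + int(np.searchsorted(prots, p))
        for d, p in known_positives
    }
    # sample flat pair codes, rejecting knowns, until enough distinct draws
    chosen: set[int] = set()
    while len(chosen) < needed:
        draw = rng.integers(0, n_all, size=2 * (needed - len(chosen)) + 8)
        for code in draw:
            code = int(code)
            if code not in pos_flat and code not in chosen:
                chosen.add(code)
                if len(chosen) == needed:
                    break
    negatives = frozenset(
        (int(drugs[code // prots.size]), int(prots[code % prots.size]))
        for code in sorted(chosen)
    )
    return InteractionSets(
        positives=frozenset(known_positives), negatives=negatives, ratio=ratio
    )


def score_pair(h_d: np.ndarray, h_p: np.ndarray) -> float:
    """Interaction probability ``sigmoid(h_d . h_p)``."""
    h_d = np.asarray(h_d, dtype=float)
    h_p = np.asarray(h_p, dtype=float)
    if h_d.shape != h_p.shape:
        raise ValueError("feature vectors must have equal length")
    return float(expit(h_d @ h_p))


def _pair_arrays(sets: InteractionSets) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted pair index arrays and +/-1 labels (deterministic order)."""
    pos = sorted(sets.positives)
    neg = sorted(sets.negatives)
    pairs = pos + neg
    d_idx = np.fromiter((d for d, _ in pairs), int, len(pairs))
    p_idx = np.fromiter((p for _, p in pairs), int, len(pairs))
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
    return d_idx, p_idx, y


def dti_loss(
    H_T_drug: np.ndarray, H_T_protein: np.ndarray, sets: InteractionSets
) -> float:
    """Logsigmoid link loss over positive and negative pairs (stable)."""
    if sets.n_pos == 0:
        raise ValueError("loss requires at least one positive pair")
    d_idx, p_idx, y = _pair_arrays(sets)
    logits = np.einsum("ij,ij->i", H_T_drug[d_idx], H_T_protein[p_idx])
    # -log sigma(y * s) = softplus(-y * s)
    return float(np.sum(np.logaddexp(0.0, -y * logits)))


def dti_loss_grad(
    H_T_drug: np.ndarray, H_T_protein: np.ndarray, sets: InteractionSets
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus analytic gradients w.r.t. both feature matrices."""
    if sets.n_pos == 0:
        raise ValueError("loss requires at least one positive pair")
    d_idx, p_idx, y = _pair_arrays(sets)
    logits = np.einsum("ij,ij->i", H_T_drug[d_idx], H_T_protein[p_idx])
    loss = float(np.sum(np.logaddexp(0.0, -y * logits)))
    dlogit = -y * expit(-y * logits)  # d softplus(-y s)/d s
    grad_d = np.zeros_like(H_T_drug)
    grad_p = np.zeros_like(H_T_protein)
    np.add.at(grad_d, d_idx, dlogit[:, None] * H_T_protein[p_idx])
    np.add.at(grad_p, p_idx, dlogit[:, None] * H_T_drug[d_idx])
    return loss, grad_d, grad_p


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class _Adam:
    """Adam over a dict of arrays keyed by slot."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            if key not in params:
                continue
            g = np.asarray(g, dtype=float)
            m = self.m.get(key)
            if m is None:
                m = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            v = self.v[key]
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.m[key], self.v[key] = m, v
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            params[key] = params[key] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Search and final training
# ---------------------------------------------------------------------------


def _role_feature_grad(
    role: str,
    H_T: np.ndarray,
    H0: np.ndarray,
    sets: InteractionSets,
) -> tuple[float, np.ndarray]:
    """Loss and dL/dH^T when only the ``role`` side is propagated.

    The opposite side's features are read from the frozen ``H^0``
    embedding, so the gradient flows only into the propagated state.
    """
    if role == "drug":
        loss, grad_d, _ = dti_loss_grad(H_T, H0, sets)
        return loss, grad_d
    loss, _, grad_p = dti_loss_grad(H0, H_T, sets)
    return loss, grad_p


def search_metagraph(
    net: HetNet,
    H0: np.ndarray,
    train_sets: InteractionSets,
    val_sets: InteractionSets,
    role: str,
    cfg: TrainConfig,
    relations: Mapping[str, NormalizedRelation] | None = None,
    catalog: RelationCatalog | None = None,
) -> tuple[MetaGraph, SignificanceTensor]:
    """Search one role's adaptive meta-graph by alternating bilevel steps.

    Every step samples an architecture (argmax-theta with decaying uniform
    exploration) and updates the GCN weights on its training loss; the
    significances are then updated on the validation loss of the
    theta-mixture supernet, which yields a dense gradient over every
    candidate of every slot.  The propagated role's features are scored
    against the frozen ``H^0`` rows of the opposite side, keeping the two
    role searches independent.  Returns the argmax meta-graph and the
    trained tensor.
    """
    if role not in ("drug", "protein"):
        raise ValueError("role must be 'drug' or 'protein'")
    if relations is None:
        relations = normalized_relations(net)
    if catalog is None:
        catalog = RelationCatalog.from_hetnet(net)
    rng = np.random.default_rng(cfg.seed)
    sig = SignificanceTensor.initialize(cfg.T, role, catalog, rng)
    weights = PropagationWeights.initialize_full(cfg.T, cfg.hidden_size, rng)
    opt_w = _Adam(cfg.learning_rate)
    opt_a = _Adam(cfg.alpha_learning_rate)

    slots = list(all_slots(cfg.T))
    # weight warm-up: the significances stay frozen while every slot's
    # weight matrix trains on uniformly explored architectures, so the
    # first architecture gradients judge candidates on comparable footing
    warm_steps = int(cfg.warmup_frac * cfg.epochs) if cfg.p0 > 0 else 0
    for step in range(cfg.epochs):
        if step == cfg.epochs // 2:
            opt_w.lr *= cfg.lr_decay
            opt_a.lr *= cfg.lr_decay
        if step < warm_steps:
            p_step = 1.0
        else:
            p_step = exploration_probability(step, cfg.epochs, cfg.p0)
        thetas = {slot: sig.theta(slot) for slot in slots}
        selections = {
            slot: select_relation(thetas[slot], sig.candidates[slot], p_step, rng)
            for slot in slots
        }

        # inner step: omega on the training loss of the sampled plan
        seq, cache = forward_cached(H0, selections, weights, relations)
        loss_tra, grad_HT = _role_feature_grad(role, seq.final, H0, train_sets)
        if not np.isfinite(loss_tra):
            raise FloatingPointError(f"training loss diverged at step {step}")
        grad_W, _ = backward(grad_HT, cache, weights, relations)
        for slot, g in grad_W.items():
            grad_W[slot] = g + cfg.weight_decay * weights.W[slot]
        opt_w.step(weights.W, grad_W)

        # outer step: alpha on the validation loss of the full mixture
        if step >= warm_steps:
            states, mcache = mixture_forward(H0, sig, weights, relations)
            loss_val, grad_HT = _role_feature_grad(role, states[-1], H0, val_sets)
            if not np.isfinite(loss_val):
                raise FloatingPointError(f"validation loss diverged at step {step}")
            grad_alpha = mixture_backward_alpha(
                grad_HT, mcache, sig, weights, relations
            )
            opt_a.step(sig.alpha, grad_alpha)

    return derive_final_metagraph(sig), sig


def train_final(
    net: HetNet,
    H0: np.ndarray,
    mg_drug: MetaGraph,
    mg_protein: MetaGraph,
    train_sets: InteractionSets,
    cfg: TrainConfig,
    relations: Mapping[str, NormalizedRelation] | None = None,
    val_sets: InteractionSets | None = None,
) -> TrainedModel:
    """Retrain fresh GCN weights on the fixed meta-graphs (joint loss).

    The drug-side and protein-side plans are propagated independently but
    optimized jointly against the link loss, so both weight sets shape the
    inner-product geometry.  When ``val_sets`` is given, the validation
    loss selects the epoch whose weights are returned (the validation set
    tunes the stopping point; held-out pairs are never touched).
    """
    if relations is None:
        relations = normalized_relations(net)
    rng = np.random.default_rng(cfg.seed)
    w_drug = PropagationWeights.initialize(mg_drug, cfg.hidden_size, rng)
    w_prot = PropagationWeights.initialize(mg_protein, cfg.hidden_size, rng)
    opt_d = _Adam(cfg.learning_rate)
    opt_p = _Adam(cfg.learning_rate)
    history: list[float] = []
    best_val = np.inf
    best_w: tuple[dict, dict] | None = None
    for epoch in range(cfg.epochs):
        if epoch == cfg.epochs // 2:
            opt_d.lr *= cfg.lr_decay
            opt_p.lr *= cfg.lr_decay
        seq_d, cache_d = forward_cached(H0, mg_drug.selected, w_drug, relations)
        seq_p, cache_p = forward_cached(H0, mg_protein.selected, w_prot, relations)
        loss, grad_d, grad_p = dti_loss_grad(seq_d.final, seq_p.final, train_sets)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        history.append(loss)
        if val_sets is not None:
            val = dti_loss(seq_d.final, seq_p.final, val_sets) / max(
                1, val_sets.n_pos + val_sets.n_neg
            )
            if val < best_val:
                best_val = val
                best_w = (
                    {k: w.copy() for k, w in w_drug.W.items()},
                    {k: w.copy() for k, w in w_prot.W.items()},
                )
        gW_d, _ = backward(grad_d, cache_d, w_drug, relations)
        gW_p, _ = backward(grad_p, cache_p, w_prot, relations)
        for slot, g in gW_d.items():
            gW_d[slot] = g + cfg.weight_decay * w_drug.W[slot]
        for slot, g in gW_p.items():
            gW_p[slot] = g + cfg.weight_decay * w_prot.W[slot]
        opt_d.step(w_drug.W, gW_d)
        opt_p.step(w_prot.W, gW_p)
    # log the loss of the weights actually returned (when no validation
    # selection applies), so freezing and re-evaluating reproduces it
    if best_w is None:
        seq_d, _ = forward_cached(H0, mg_drug.selected, w_drug, relations)
        seq_p, _ = forward_cached(H0, mg_protein.selected, w_prot, relations)
        history.append(dti_loss(seq_d.final, seq_p.final, train_sets))
    if best_w is not None:
        w_drug = PropagationWeights(W=best_w[0])
        w_prot = PropagationWeights(W=best_w[1])
    return TrainedModel(
        metagraph_drug=mg_drug,
        metagraph_protein=mg_protein,
        weights_drug=w_drug,
        weights_protein=w_prot,
        H0=np.asarray(H0, dtype=float),
        loss_history=history,
    )


def save_model(model: TrainedModel, path) -> None:
    """JSON checkpoint of both meta-graphs and their weight matrices.

    ``H^0`` is not stored (it lives in the embedding cache); pass it back
    to :func:`load_model`.
    """
    import json

    def pack(w: PropagationWeights) -> dict:
        return {f"{i},{t}": m.tolist() for (i, t), m in sorted(w.W.items())}

    payload = {
        "metagraph_drug": json.loads(model.metagraph_drug.to_json()),
        "metagraph_protein": json.loads(model.metagraph_protein.to_json()),
        "weights_drug": pack(model.weights_drug),
        "weights_protein": pack(model.weights_protein),
        "loss_history": model.loss_history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_model(path, H0: np.ndarray) -> TrainedModel:
    """Rebuild a :class:`TrainedModel` from a JSON checkpoint plus ``H^0``."""
    import json

    with open(path) as fh:
        payload = json.load(fh)

    def unpack_mg(obj: dict) -> MetaGraph:
        selected = {
            tuple(int(x) for x in key.split(",")): mode
            for key, mode in obj["selected"].items()
        }
        return MetaGraph(T=obj["T"], role=obj["role"], selected=selected)

    def unpack_w(obj: dict) -> PropagationWeights:
        return PropagationWeights(
            W={
                tuple(int(x) for x in key.split(",")): np.asarray(m, dtype=float)
                for key, m in obj.items()
            }
        )

    return TrainedModel(
        metagraph_drug=unpack_mg(payload["metagraph_drug"]),
        metagraph_protein=unpack_mg(payload["metagraph_protein"]),
        weights_drug=unpack_w(payload["weights_drug"]),
        weights_protein=unpack_w(payload["weights_protein"]),
        H0=np.asarray(H0, dtype=float),
        loss_history=list(payload.get("loss_history", [])),
    )


def predict_ranked(
    model: TrainedModel,
    relations: Mapping[str, NormalizedRelation],
    candidate_pairs: set[tuple[int, int]],
    top_k: int | None = None,
) -> list[PairScore]:
    """Score candidate pairs and rank them by descending probability.

    Ties are broken by ascending (drug index, protein index) so the
    ordering is stable and reproducible.
    """
    if not candidate_pairs:
        return []
    F_d, F_p = model.features(relations)
    pairs = sorted(candidate_pairs)
    d_idx = np.fromiter((d for d, _ in pairs), int, len(pairs))
    p_idx = np.fromiter((p for _, p in pairs), int, len(pairs))
    logits = np.einsum("ij,ij->i", F_d[d_idx], F_p[p_idx])
    scores = expit(logits)
    order = sorted(range(len(pairs)), key=lambda k: (-scores[k], pairs[k]))
    if top_k is not None:
        order = order[:top_k]
    return [
        PairScore(drug=int(d_idx[k]), protein=int(p_idx[k]), score=float(scores[k]))
        for k in order
    ]
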