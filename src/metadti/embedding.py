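"""Initial node representations: node2vec walks + skip-gram, or one-hot.

The propagation states start from ``H^0``, an N x d matrix of node
features.  The default encoder runs biased second-order random walks over
the directionless union of all relations and trains a skip-gram model with
negative sampling on the resulting node sequences, so that nodes sharing
neighborhoods end up with similar vectors.  A one-hot identity encoding is
provided as the ablation variant.

The skip-gram trainer is a vectorized SGD implementation of skip-gram with
negative sampling (SGNS): positive (center, context) pairs are extracted
from every walk within a symmetric window, negatives are drawn uniformly
over nodes, and both input and output embeddings are updated in mini
batches.  The returned embedding is the input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .hetnet import HetNet, build_relation_matrix

__all__ = [
    "WalkCorpus",
    "EmbeddingMatrix",
    "generate_walks",
    "train_skipgram",
    "one_hot_embeddings",
    "node2vec_embeddings",
]


@dataclass
class WalkCorpus:
    """Random-walk node sequences plus the walk parameters that made them."""

    walks: list[np.ndarray]
    walk_length: int
    walks_per_node: int
    p: float
    q: float


@dataclass
class EmbeddingMatrix:
    """N x d node-feature matrix ``H^0`` with its provenance tag."""

    H: np.ndarray
    source: str  # "node2vec" | "one-hot"


def _union_adjacency(net: HetNet) -> sp.csr_matrix:
    """Directionless union of all relations as a binary CSR adjacency."""
    n = net.n_nodes
    acc = sp.csr_matrix((n, n))
    for name in net.relation_names():
        acc = acc + build_relation_matrix(net, name).matrix
    acc = acc + acc.T
    acc.data[:] = 1.0
    acc.eliminate_zeros()
    return acc.tocsr()


def generate_walks(
    net: HetNet,
    ws: int = 100,
    nw: int = 15,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> WalkCorpus:
    """Run ``nw`` random walks of length <= ``ws`` from every node.

    Walks move on the directionless union of all relations.  With
    ``p = q = 1`` the walk is a uniform first-order random walk (fast
    vectorized path); otherwise the standard second-order return/in-out
    bias is applied.  Dead-end nodes terminate their walk early.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot walk on an empty network")
    if ws < 2 or nw < 1 or p <= 0 or q <= 0:
        raise ValueError("require ws >= 2, nw >= 1, p > 0, q > 0")
    adj = _union_adjacency(net)
    indptr, indices = adj.indptr, adj.indices
    degrees = np.diff(indptr)
    rng = np.random.default_rng(seed)
    n = net.n_nodes

    walks: list[np.ndarray] = []
    if p == 1.0 and q == 1.0:
        starts = np.repeat(np.arange(n), nw)
        n_walkers = starts.size
        buf = np.full((n_walkers, ws), -1, dtype=np.int64)
        buf[:, 0] = starts
        current = starts.copy()
        alive = degrees[current] > 0
        for step in range(1, ws):
            if not alive.any():
                break
            cur = current[alive]
            r = rng.random(cur.size)
            nxt = indices[indptr[cur] + (r * degrees[cur]).astype(np.int64)]
            current[alive] = nxt
            buf[alive, step] = nxt
            alive[alive] = degrees[nxt] > 0
        for row in buf:
            walks.append(row[row >= 0].copy())
    else:
        neighbor_sets = [
            set(indices[indptr[v]: indptr[v + 1]]) for v in range(n)
        ]
        for start in range(n):
            for _ in range(nw):
                walk = [start]
                while len(walk) < ws:
                    cur = walk[-1]
                    nbrs = indices[indptr[cur]: indptr[cur + 1]]
                    if nbrs.size == 0:
                        break
                    if len(walk) == 1:
                        nxt = int(rng.choice(nbrs))
                    else:
                        prev = walk[-2]
                        w = np.empty(nbrs.size)
                        for k, x in enumerate(nbrs):
                            if x == prev:
                                w[k] = 1.0 / p
                            elif x in neighbor_sets[prev]:
                                w[k] = 1.0
                            else:
                                w[k] = 1.0 / q
                        w /= w.sum()
                        nxt = int(rng.choice(nbrs, p=w))
                    walk.append(nxt)
                walks.append(np.asarray(walk, dtype=np.int64))
    return WalkCorpus(walks=walks, walk_length=ws, walks_per_node=nw, p=p, q=q)


def _window_pairs(corpus: WalkCorpus, window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) pairs within the symmetric window, both directions."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for walk in corpus.walks:
        L = walk.size
        for k in range(1, min(window, L - 1) + 1):
            a, b = walk[:-k], walk[k:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def train_skipgram(
    corpus: WalkCorpus,
    n_nodes: int,
    d: int = 64,
    window: int = 5,
    negatives_per_positive: int = 5,
    epochs: int = 5,
    lr: float = 0.025,
    seed: int = 0,
    batch_size: int = 2048,
) -> EmbeddingMatrix:
    """Train skip-gram with negative sampling on a walk corpus.

    Nodes absent from every walk keep their small random initialization.
    The learning rate decays linearly over batches, as in word2vec.
    """
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    rng = np.random.default_rng(seed)
    W_in = (rng.random((n_nodes, d)) - 0.5) / d
    W_out = np.zeros((n_nodes, d))

    centers, contexts = _window_pairs(corpus, window)
    if centers.size == 0:
        return EmbeddingMatrix(H=W_in, source="node2vec")
    n_pairs = centers.size
    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            idx = order[lo: lo + batch_size]
            c, o = centers[idx], contexts[idx]
            neg = rng.integers(0, n_nodes, size=(idx.size, negatives_per_positive))
            eta = lr * max(1e-4, 1.0 - batch_no / total_batches)
            batch_no += 1

            vc = W_in[c]  # (B, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (B, 1+K)
            vt = W_out[targets]  # (B, 1+K, d)
            logits = np.einsum("bd,bkd->bk", vc, vt)
            sig = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
            # gradient of -log sigma(s) for the true context (label 1)
            # and -log sigma(-s) for negatives (label 0)
            labels = np.zeros_like(sig)
            labels[:, 0] = 1.0
            err = sig - labels  # (B, 1+K)
            grad_c = np.einsum("bk,bkd->bd", err, vt)
            grad_t = err[:, :, None] * vc[:, None, :]
            # average (not sum) per-row gradients: a node occurring many
            # times in a batch would otherwise take a step proportional to
            # its multiplicity and diverge on small vocabularies
            acc_in = np.zeros_like(W_in)
            np.add.at(acc_in, c, grad_c)
            cnt_in = np.bincount(c, minlength=n_nodes)[:, None]
            W_in -= eta * acc_in / np.maximum(cnt_in, 1)
            acc_out = np.zeros_like(W_out)
            flat_t = targets.ravel()
            np.add.at(acc_out, flat_t, grad_t.reshape(-1, d))
            cnt_out = np.bincount(flat_t, minlength=n_nodes)[:, None]
            W_out -= eta * acc_out / np.maximum(cnt_out, 1)
    return EmbeddingMatrix(H=W_in, source="node2vec")


def one_hot_embeddings(net: HetNet) -> EmbeddingMatrix:
    """Identity encoding: each node is its own indicator feature (d = N)."""
    return EmbeddingMatrix(H=np.eye(net.n_nodes), source="one-hot")


def node2vec_embeddings(
    net: HetNet,
    d: int = 64,
    ws: int = 100,
    nw: int = 15,
    p: float = 1.0,
    q: float = 1.0,
    window: int = 5,
    negatives_per_positive: int = 5,
    epochs: int = 5,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Walks plus skip-gram in one call; the standard ``H^0`` encoder."""
    corpus = generate_walks(net, ws=ws, nw=nw, p=p, q=q, seed=seed)
    return train_skipgram(
        corpus,
        n_nodes=net.n_nodes,
        d=d,
        window=window,
        negatives_per_positive=negatives_per_positive,
        epochs=epochs,
        seed=seed + 1,
    )


def save_embeddings(emb: EmbeddingMatrix, net: HetNet, path: str | Path) -> None:
    """Write a TSV cache ``node_id <tab> v1..vd`` in catalog order."""
    df = pd.DataFrame(emb.H)
    df.insert(0, "node_id", net.catalog.ids)
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.10g")


def load_embeddings(net: HetNet, path: str | Path, source: str = "node2vec") -> EmbeddingMatrix:
    """Read an embedding TSV written by :func:`save_embeddings`."""
    df = pd.read_csv(path, sep="\t", header=None)
    ids = list(df[0])
    if ids != list(net.catalog.ids):
        raise ValueError("embedding cache does not match the network's catalog")
    return EmbeddingMatrix(H=df.iloc[:, 1:].to_numpy(float), source=source)
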