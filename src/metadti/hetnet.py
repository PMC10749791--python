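"""Heterogeneous-network data model and typed relation matrices.

A heterogeneous biomedical network couples several node types (drug,
protein, disease, side-effect, ...) through directed, typed relations.
Everything downstream -- random-walk embeddings, meta-graph search, GCN
propagation -- operates on the node catalog and per-relation adjacency
matrices defined here.

Conventions
-----------
* Nodes are globally ordered by ``(node_type, node_id)``; all matrices and
  embedding rows use this ordering.
* A relation matrix ``R`` follows the receiver-row convention:
  ``R[v, u] = 1`` when information flows from sender ``u`` to receiver ``v``.
  Consequently the matrix of relation A->B is exactly the transpose of the
  matrix of B->A.
* Relations between distinct node types always come in transpose-closed
  pairs; a same-type relation (drug-drug, protein-protein) is stored
  symmetrized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "NodeCatalog",
    "HetNet",
    "RelationMatrix",
    "NormalizedRelation",
    "load_hetnet",
    "save_hetnet",
    "build_relation_matrix",
    "normalize_relation",
    "transpose_name",
]


class HetNetError(ValueError):
    """Raised for malformed node tables, edge lists or relation typing."""


def transpose_name(relation_name: str) -> str:
    """Name of the reverse relation for a ``<src>_<dst>`` relation name."""
    src, _, dst = relation_name.partition("_")
    if not dst:
        raise HetNetError(
            f"relation name {relation_name!r} is not of the form '<src>_<dst>'"
        )
    return f"{dst}_{src}"


@dataclass(frozen=True)
class NodeCatalog:
    """Global node ordering: ids, types and dense indices.

    Nodes are sorted by ``(type, id)`` so that the ordering -- and hence
    every matrix built on top of it -- is reproducible from the node table
    alone.
    """

    ids: tuple[str, ...]
    types: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "NodeCatalog":
        pairs = list(pairs)
        seen: dict[str, str] = {}
        for node_id, node_type in pairs:
            if node_id in seen:
                raise HetNetError(f"duplicate node id {node_id!r}")
            seen[node_id] = node_type
        ordered = sorted(pairs, key=lambda p: (p[1], p[0]))
        ids = tuple(p[0] for p in ordered)
        types = tuple(p[1] for p in ordered)
        return cls(ids=ids, types=types, index={i: k for k, i in enumerate(ids)})

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def type_set(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.types)))

    def indices_of_type(self, node_type: str) -> np.ndarray:
        """Dense indices of all nodes of ``node_type`` (ascending)."""
        return np.flatnonzero(np.asarray(self.types) == node_type)

    def type_of(self, idx: int) -> str:
        return self.types[idx]


@dataclass
class HetNet:
    """Node catalog plus directed, typed, transpose-closed relations.

    ``relations`` maps a relation name to a set of ``(source index,
    target index)`` edges; ``relation_typing`` maps the same name to its
    ``(source type, target type)`` pair.
    """

    catalog: NodeCatalog
    relations: dict[str, set[tuple[int, int]]]
    relation_typing: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        catalog: NodeCatalog,
        relations: Mapping[str, Iterable[tuple[int, int]]],
        relation_typing: Mapping[str, tuple[str, str]],
    ) -> "HetNet":
        """Build a network, materializing missing reverse relations.

        Same-type relations are symmetrized in place; cross-type relations
        get an explicit transposed twin if one was not supplied.
        """
        rel: dict[str, set[tuple[int, int]]] = {
            name: set(map(tuple, edges)) for name, edges in relations.items()
        }
        typing = {name: tuple(t) for name, t in relation_typing.items()}
        for name in list(rel):
            src_t, dst_t = typing[name]
            if src_t == dst_t:
                rel[name] |= {(v, u) for u, v in rel[name]}
            else:
                rev = transpose_name(name)
                transposed = {(v, u) for u, v in rel[name]}
                if rev in rel:
                    rel[rev] |= transposed
                    rel[name] |= {(v, u) for u, v in rel[rev]}
                else:
                    rel[rev] = transposed
                typing.setdefault(rev, (dst_t, src_t))
        return cls(catalog=catalog, relations=rel, relation_typing=typing)

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        n = len(self.catalog)
        types = self.catalog.types
        for name, edges in self.relations.items():
            if name not in self.relation_typing:
                raise HetNetError(f"relation {name!r} has no declared typing")
            src_t, dst_t = self.relation_typing[name]
            for u, v in edges:
                if not (0 <= u < n and 0 <= v < n):
                    raise HetNetError(f"edge ({u},{v}) in {name!r} out of range")
                if types[u] != src_t or types[v] != dst_t:
                    raise HetNetError(
                        f"edge ({u},{v}) in {name!r} violates typing "
                        f"{src_t}->{dst_t} (got {types[u]}->{types[v]})"
                    )
            rev = name if src_t == dst_t else transpose_name(name)
            if rev not in self.relations:
                raise HetNetError(f"relation {name!r} lacks reverse {rev!r}")
            if {(v, u) for u, v in edges} != self.relations[rev]:
                raise HetNetError(
                    f"relation {name!r} is not the transpose of {rev!r}"
                )

    # -- convenience --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.catalog)

    def relation_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.relations))

    def edge_counts(self) -> dict[str, int]:
        return {name: len(edges) for name, edges in sorted(self.relations.items())}


@dataclass(frozen=True)
class RelationMatrix:
    """Binary N x N adjacency of one relation, receiver-row convention."""

    relation_name: str
    matrix: sp.csr_matrix
    n: int


@dataclass(frozen=True)
class NormalizedRelation:
    """Symmetrically degree-normalized relation with self-loops.

    Stores ``D_r^{-1/2} (R + I) D_c^{-1/2}`` where ``D_r``/``D_c`` are the
    diagonal row/column degree matrices of ``R + I``.  For a symmetric
    relation the two coincide and this is the standard GCN normalization.
    Self-loops guarantee every degree is >= 1, so the scaling is always
    well defined.
    """

    base: RelationMatrix
    normalized: sp.csr_matrix


def build_relation_matrix(net: HetNet, relation_name: str) -> RelationMatrix:
    """N x N binary matrix of a relation; entry ``[v, u] = 1`` for edge u->v."""
    if relation_name not in net.relations:
        raise HetNetError(f"unknown relation {relation_name!r}")
    n = net.n_nodes
    edges = net.relations[relation_name]
    if edges:
        senders, receivers = zip(*edges)
        mat = sp.csr_matrix(
            (np.ones(len(edges)), (receivers, senders)), shape=(n, n)
        )
    else:
        mat = sp.csr_matrix((n, n))
    return RelationMatrix(relation_name=relation_name, matrix=mat, n=n)


def normalize_relation(rel: RelationMatrix) -> NormalizedRelation:
    """Apply ``D_r^{-1/2} (R + I) D_c^{-1/2}`` degree normalization."""
    n = rel.n
    r_tilde = (rel.matrix + sp.identity(n, format="csr")).tocsr()
    row_deg = np.asarray(r_tilde.sum(axis=1)).ravel()
    col_deg = np.asarray(r_tilde.sum(axis=0)).ravel()
    d_r = sp.diags(1.0 / np.sqrt(row_deg))
    d_c = sp.diags(1.0 / np.sqrt(col_deg))
    return NormalizedRelation(base=rel, normalized=(d_r @ r_tilde @ d_c).tocsr())


def normalized_relations(net: HetNet) -> dict[str, NormalizedRelation]:
    """Normalized matrices for every relation of the network."""
    return {
        name: normalize_relation(build_relation_matrix(net, name))
        for name in net.relation_names()
    }


# ---------------------------------------------------------------------------
# TSV / manifest I/O
# ---------------------------------------------------------------------------


def load_hetnet(
    node_table_path: str | Path,
    relation_files: Mapping[str, str | Path],
    relation_typing: Mapping[str, tuple[str, str]],
) -> HetNet:
    """Load a network from a node table and per-relation edge lists.

    The node table is a TSV with header columns ``id`` and ``type``; each
    edge file is a headerless two-column TSV of node ids (source, target).
    Reverse relations not present on disk are materialized as transposes.
    """
    node_table_path = Path(node_table_path)
    table = pd.read_csv(node_table_path, sep="\t", dtype=str)
    if not {"id", "type"}.issubset(table.columns):
        raise HetNetError(f"{node_table_path} must have columns 'id' and 'type'")
    catalog = NodeCatalog.from_pairs(zip(table["id"], table["type"]))

    relations: dict[str, set[tuple[int, int]]] = {}
    for name, path in relation_files.items():
        if name not in relation_typing:
            raise HetNetError(f"relation {name!r} missing from relation_typing")
        path = Path(path)
        edges: set[tuple[int, int]] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise HetNetError(
                        f"{path}:{lineno}: expected two tab-separated ids"
                    )
                for node_id in parts:
                    if node_id not in catalog.index:
                        raise HetNetError(
                            f"{path}:{lineno}: unknown node id {node_id!r}"
                        )
                edges.add((catalog.index[parts[0]], catalog.index[parts[1]]))
        key = (name, tuple(relation_typing[name]))
        relations.setdefault(key[0], set()).update(edges)

    net = HetNet.from_edges(
        catalog,
        relations,
        {name: tuple(relation_typing[name]) for name in relations},
    )
    return net


def load_hetnet_from_manifest(manifest_path: str | Path) -> HetNet:
    """Load a network described by a YAML/JSON manifest.

    The manifest carries ``nodes`` (node-table path), and ``relations``:
    a mapping relation name -> ``{file, source_type, target_type}``.  Paths
    are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        if manifest_path.suffix in {".yaml", ".yml"}:
            manifest = yaml.safe_load(fh)
        else:
            manifest = json.load(fh)
    base = manifest_path.parent
    relation_files = {
        name: base / spec["file"] for name, spec in manifest["relations"].items()
    }
    relation_typing = {
        name: (spec["source_type"], spec["target_type"])
        for name, spec in manifest["relations"].items()
    }
    return load_hetnet(base / manifest["nodes"], relation_files, relation_typing)


def save_hetnet(net: HetNet, out_dir: str | Path) -> Path:
    """Write node table, edge lists and a JSON manifest; returns manifest path.

    Only one member of each transpose-closed pair is written (the
    lexicographically smaller name); reloading reconstructs the reverse.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame({"id": net.catalog.ids, "type": net.catalog.types})
    nodes.to_csv(out_dir / "nodes.tsv", sep="\t", index=False)

    manifest: dict = {"nodes": "nodes.tsv", "relations": {}}
    for name in net.relation_names():
        src_t, dst_t = net.relation_typing[name]
        rev = name if src_t == dst_t else transpose_name(name)
        if rev < name:  # written under the partner's name
            continue
        fname = f"{name}.tsv"
        ids = net.catalog.ids
        rows = sorted(
            (ids[u], ids[v]) for u, v in net.relations[name]
        )
        with open(out_dir / fname, "w") as fh:
            for u_id, v_id in rows:
                fh.write(f"{u_id}\t{v_id}\n")
        manifest["relations"][name] = {
            "file": fname,
            "source_type": src_t,
            "target_type": dst_t,
        }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path
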