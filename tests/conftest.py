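"""Shared fixtures: tiny in-memory networks and the default planted fixture.

The planted network and its node2vec encoding are session-scoped because
the encoder dominates runtime; search/training tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from metadti.embedding import node2vec_embeddings
from metadti.hetnet import HetNet, NodeCatalog
from metadti.metagraph import RelationCatalog
from metadti.synthetic import PlantedSpec, generate_planted_hetnet


@pytest.fixture()
def toy_net() -> HetNet:
    """3 drugs, 2 proteins, 1 disease with a couple of typed relations."""
    catalog = NodeCatalog.from_pairs(
        [
            ("d1", "drug"),
            ("d2", "drug"),
            ("d3", "drug"),
            ("p1", "protein"),
            ("p2", "protein"),
            ("e1", "disease"),
        ]
    )
    idx = catalog.index
    relations = {
        "drug_protein": {(idx["d1"], idx["p1"]), (idx["d2"], idx["p2"])},
        "drug_disease": {(idx["d1"], idx["e1"]), (idx["d3"], idx["e1"])},
        "disease_protein": {(idx["e1"], idx["p2"])},
        "drug_drug": {(idx["d1"], idx["d2"])},
    }
    typing = {
        "drug_protein": ("drug", "protein"),
        "drug_disease": ("drug", "disease"),
        "disease_protein": ("disease", "protein"),
        "drug_drug": ("drug", "drug"),
    }
    return HetNet.from_edges(catalog, relations, typing)


@pytest.fixture()
def na_catalog() -> RelationCatalog:
    """12-mode catalog shaped like a 4-type drug/protein/disease/side-effect
    network with all ten directed relation types plus IDENTITY and NULL."""
    targets = {
        "drug_protein": "protein",
        "protein_drug": "drug",
        "drug_side-effect": "side-effect",
        "side-effect_drug": "drug",
        "drug_disease": "disease",
        "disease_drug": "drug",
        "protein_disease": "disease",
        "disease_protein": "protein",
        "drug_drug": "drug",
        "protein_protein": "protein",
    }
    return RelationCatalog.from_relations(targets)


@pytest.fixture(scope="session")
def planted():
    """The default planted fixture (two-hop drug-disease-protein rule)."""
    return generate_planted_hetnet(PlantedSpec())


@pytest.fixture(scope="session")
def planted_H0(planted) -> np.ndarray:
    """Node2vec encoding of the planted fixture (computed once).

    Seeded exactly as ``AdaptiveMetaGraphDTI.encode(seed=0)`` derives it,
    so search/training tests reproduce full-pipeline runs.
    """
    from metadti.model import derive_seed

    return node2vec_embeddings(planted.net, d=64, seed=derive_seed(0, "embed")).H


@pytest.fixture(scope="session")
def small_planted():
    """A smaller, denser planted network for fast search/training smoke tests."""
    spec = PlantedSpec(
        counts={"drug": 16, "protein": 10, "disease": 6, "side-effect": 5},
        densities={
            "drug_drug": 0.05,
            "protein_protein": 0.05,
            "drug_side-effect": 0.05,
            "drug_disease": 0.2,
            "disease_protein": 0.2,
        },
        seed=3,
    )
    return generate_planted_hetnet(spec)
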