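"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from gnnma.model import GNNMAScorer, ModelConfig
from gnnma.molgraph import FeatureSchema, smiles_to_graph
from gnnma.synthetic import SyntheticSpec, generate_library


@pytest.fixture(scope="session")
def schema():
    return FeatureSchema()


@pytest.fixture(scope="session")
def tiny_library():
    """Two-target screening library, small enough for fast training."""
    return generate_library(SyntheticSpec(
        n_targets=2, actives_per_target=8, decoys_per_target=30, seed=5))


@pytest.fixture(scope="session")
def tiny_graphs(tiny_library, schema):
    return {row.mol_id: smiles_to_graph(row.smiles, schema, mol_id=row.mol_id)
            for row in tiny_library.itertuples()}


@pytest.fixture(scope="session")
def small_scorer(schema):
    """Low-dimensional scorer with dropout off, for exact numeric checks."""
    cfg = ModelConfig(hidden_dim=8, mlp_hidden=(8,), dropout=0.0)
    return GNNMAScorer(cfg, schema, seed=3)


@pytest.fixture(scope="session")
def molecule_pool(schema):
    """A diverse set of featurized molecules for randomized pair tests."""
    smiles = [
        "C", "CC", "CCO", "c1ccccc1", "Cc1ccccc1", "c1ccncc1",
        "CC(=O)O", "CC(=O)Nc1ccc(O)cc1", "C1CCNCC1", "Clc1cccc(Br)c1",
        "N#Cc1ccc(CO)cc1", "COc1ccc(C(N)=O)cn1", "CC(C)c1ccsc1",
        "OCC1CCN(C)C1", "Fc1cnc(N)nc1",
    ]
    return [smiles_to_graph(s, schema, mol_id=f"m{i}")
            for i, s in enumerate(smiles)]
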