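import numpy as np
import pytest

from kglink import (
    Entity,
    KnowledgeGraph,
    RelationType,
    SyntheticConfig,
    Triple,
    generate_synthetic_kg,
)


@pytest.fixture
def tiny_kg() -> KnowledgeGraph:
    """Five genes, three diseases, two relations; hand-countable."""
    entities = [Entity(f"G{i}", "GeneProtein") for i in range(1, 6)]
    entities += [Entity(f"D{i}", "Disease") for i in range(1, 4)]
    relations = [
        RelationType("therapeutic_relationship", "Disease", "GeneProtein"),
        RelationType("association", "Disease", "GeneProtein"),
    ]
    triples = [
        Triple("D1", "therapeutic_relationship", "G1", 2001),
        Triple("D1", "therapeutic_relationship", "G2", 2005),
        Triple("D1", "therapeutic_relationship", "G3"),
        Triple("D2", "therapeutic_relationship", "G2", 2010),
        Triple("D2", "therapeutic_relationship", "G4", 2015),
        Triple("D3", "therapeutic_relationship", "G5", 1999),
        Triple("D1", "association", "G4"),
        Triple("D2", "association", "G1"),
        Triple("D3", "association", "G2"),
        Triple("D3", "association", "G3"),
    ]
    return KnowledgeGraph(entities, relations, triples)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted graph shared by tests that only read it."""
    cfg = SyntheticConfig(
        entities_per_type={
            "GeneProtein": 60,
            "Disease": 20,
            "GOProcess": 15,
            "Pathway": 10,
            "Compound": 45,
        },
        true_dim=4,
        edge_density=0.06,
        seed=7,
    )
    return generate_synthetic_kg(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
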