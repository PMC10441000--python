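import numpy as np
import pytest

from kgxplain.kg_store import BioEdge, BioNode, KnowledgeGraph
from kgxplain.synthetic_kg import SynthConfig, generate


def make_graph(node_specs, edge_specs, **kwargs):
    """node_specs: (id, category) tuples; edge_specs: (s, p, o) tuples."""
    nodes = {
        nid: BioNode(id=nid, name=f"name of {nid}", category=cat)
        for nid, cat in node_specs
    }
    edges = [BioEdge(s, p, o, source="test") for s, p, o in edge_specs]
    return KnowledgeGraph(nodes=nodes, edges=edges, **kwargs)


@pytest.fixture
def toy_graph():
    """Drug -> Gene -> Disease plus clutter; used across module tests."""
    return make_graph(
        [
            ("D1", "Drug"), ("D2", "Drug"),
            ("Z1", "Disease"), ("Z2", "Disease"),
            ("G1", "Gene"), ("G2", "Gene"), ("P1", "Pathway"),
        ],
        [
            ("D1", "targets", "G1"),
            ("D1", "interacts_with", "G1"),
            ("G1", "associated_with", "Z1"),
            ("G1", "participates_in", "P1"),
            ("P1", "associated_with", "Z1"),
            ("D2", "targets", "G2"),
            ("G2", "associated_with", "Z2"),
            ("G2", "interacts_with", "G1"),
        ],
    )


@pytest.fixture(scope="session")
def small_fixture():
    """Session-wide synthetic KG with planted 3-hop mechanisms."""
    return generate(
        SynthConfig(
            n_drugs=40, n_diseases=40, n_genes=50, n_pathways=12,
            n_treat_pairs=30, n_not_treat_pairs=15,
            mechanism_hops=3, decoy_edge_rate=2.0, seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_fixture_embeddings(small_fixture):
    from kgxplain.node_embeddings import (
        GraphEmbedConfig,
        attribute_embeddings,
        reduce_pca,
        train_graph_embeddings,
    )

    g = small_fixture.graph
    attr = reduce_pca(attribute_embeddings(g), target_dim=32)
    emb = train_graph_embeddings(
        g, attr,
        GraphEmbedConfig(epochs=3, hidden_dim=32, num_negatives=5, seed=0),
    )
    return attr, emb


@pytest.fixture(scope="session")
def small_fixture_drp(small_fixture, small_fixture_embeddings):
    from kgxplain.drp import fit_drp, pair_features
    from kgxplain.pair_data import (
        SplitConfig, TREAT, sample_unknown_pairs, split_by_drug,
    )

    _, emb = small_fixture_embeddings
    g = small_fixture.graph
    pairs = split_by_drug(small_fixture.pairs, SplitConfig(seed=0))
    unknowns = sample_unknown_pairs(
        [p for p in pairs if p.label == TREAT], pairs,
        g.drug_ids(), g.disease_ids(), seed=0,
    )
    train = [p for p in pairs if p.split == "train"] + unknowns
    model = fit_drp(pair_features(emb, train), seed=0, n_estimators=60)
    return pairs, model
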