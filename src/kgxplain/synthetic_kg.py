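"""Seeded synthetic knowledge graphs with planted treatment structure.

``generate`` emits a four-category graph (Drug / Gene / Pathway / Disease)
in which every planted treat pair is connected by a mechanism path through
a known drug target, decoy edges add realistic clutter, and a publication
co-occurrence map gives consecutive mechanism nodes many shared
publications (Poisson ``pub_lambda_signal``) while random pairs share few
(Poisson ``pub_lambda_noise``).  Everything is reproducible from the seed
and round-trips through the package's loaders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .demo_paths import KGPath
from .kg_store import BioEdge, BioNode, KnowledgeGraph
from .literature_ngd import ConceptPubMap
from .pair_data import LabeledPair, NOT_TREAT, TREAT


@dataclass(frozen=True)
class SynthConfig:
    n_drugs: int = 60
    n_diseases: int = 60
    n_genes: int = 80
    n_pathways: int = 20
    n_treat_pairs: int = 40
    n_not_treat_pairs: int = 20
    mechanism_hops: int = 2  # 2: drug->gene->disease; 3: drug->gene->pathway->disease
    targets_per_pair: int = 1  # parallel mechanism paths planted per treat pair
    # communities model drug classes / disease families: labeled pairs are
    # sampled within a community and mechanism genes come from the
    # community's gene pool; 1 = no community structure
    n_communities: int = 1
    decoy_edge_rate: float = 1.0  # decoy edges per node, on average
    pub_lambda_signal: float = 30.0
    pub_lambda_noise: float = 1.0
    n_background_pubs: int = 30
    total_pairs: int = 10_000_000
    # restrict labeled pairs to the first n_active_* drugs/diseases, so pairs
    # concentrate on few drugs while the full pools stay available as
    # replacement candidates; None = use the whole grid
    n_active_drugs: int | None = None
    n_active_diseases: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_diseases", "n_genes", "n_pathways",
                     "n_treat_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mechanism_hops not in (2, 3):
            raise ValueError("mechanism_hops must be 2 or 3")
        if self.pub_lambda_signal <= self.pub_lambda_noise:
            raise ValueError("pub_lambda_signal must exceed pub_lambda_noise")
        active = self.active_grid()
        if self.n_treat_pairs + self.n_not_treat_pairs > active[0] * active[1]:
            raise ValueError("more labeled pairs than drug x disease combinations")
        if self.n_communities > min(self.n_genes, self.n_pathways):
            raise ValueError("n_communities exceeds gene/pathway pool size")

    def active_grid(self) -> tuple[int, int]:
        return (
            min(self.n_active_drugs or self.n_drugs, self.n_drugs),
            min(self.n_active_diseases or self.n_diseases, self.n_diseases),
        )


@dataclass
class GroundTruth:
    treat_pairs: list[LabeledPair]
    not_treat_pairs: list[LabeledPair]
    mechanism_paths: list[KGPath]
    drug_targets: list[tuple[str, str]]

    def to_json(self) -> dict:
        return {
            "treat_pairs": [[p.drug, p.disease] for p in self.treat_pairs],
            "not_treat_pairs": [[p.drug, p.disease] for p in self.not_treat_pairs],
            "mechanism_paths": [
                {"nodes": list(p.nodes), "predicates": list(p.predicates)}
                for p in self.mechanism_paths
            ],
            "drug_targets": [list(t) for t in self.drug_targets],
        }


@dataclass
class SyntheticFixture:
    graph: KnowledgeGraph
    pairs: list[LabeledPair]
    pub_map: ConceptPubMap
    truth: GroundTruth


def generate(cfg: SynthConfig) -> SyntheticFixture:
    rng = np.random.default_rng(cfg.seed)
    drugs = [f"DRUG:{i:04d}" for i in range(cfg.n_drugs)]
    diseases = [f"DIS:{i:04d}" for i in range(cfg.n_diseases)]
    genes = [f"GENE:{i:04d}" for i in range(cfg.n_genes)]
    pathways = [f"PW:{i:04d}" for i in range(cfg.n_pathways)]

    nodes = {}
    for ids, cat, stem in (
        (drugs, "Drug", "drug"),
        (diseases, "Disease", "disease"),
        (genes, "Gene", "gene"),
        (pathways, "Pathway", "pathway"),
    ):
        for i, v in enumerate(ids):
            nodes[v] = BioNode(id=v, name=f"{stem} {i}", category=cat)

    # labeled pairs: sample without replacement from the active drug x disease
    # grid, restricted to within-community pairs
    n_label = cfg.n_treat_pairs + cfg.n_not_treat_pairs
    a_drugs, a_diseases = cfg.active_grid()
    k = max(1, cfg.n_communities)
    eligible = [
        (i, j)
        for i in range(a_drugs)
        for j in range(a_diseases)
        if i % k == j % k
    ]
    if n_label > len(eligible):
        raise ValueError("more labeled pairs than within-community combinations")
    chosen = rng.choice(len(eligible), size=n_label, replace=False)
    pair_ids = [(drugs[eligible[c][0]], diseases[eligible[c][1]])
                for c in chosen]
    community_of = {drugs[i]: i % k for i in range(a_drugs)}
    gene_pools = [[g for gi, g in enumerate(genes) if gi % k == c]
                  for c in range(k)]
    pathway_pools = [[p for pi, p in enumerate(pathways) if pi % k == c]
                     for c in range(k)]
    treat_keys = pair_ids[: cfg.n_treat_pairs]
    not_treat_keys = pair_ids[cfg.n_treat_pairs:]

    edge_set: dict[tuple[str, str, str], BioEdge] = {}

    def add_edge(s: str, p: str, o: str, source: str = "synthetic") -> None:
        key = (s, p, o)
        if key not in edge_set:
            edge_set[key] = BioEdge(s, p, o, source=source)

    mechanism_paths: list[KGPath] = []
    drug_targets: list[tuple[str, str]] = []
    signal_pairs: set[tuple[str, str]] = set()
    for drug, disease in treat_keys:
        pool = gene_pools[community_of[drug]]
        pw_pool = pathway_pools[community_of[drug]]
        for _ in range(cfg.targets_per_pair):
            gene = pool[rng.integers(len(pool))]
            drug_targets.append((drug, gene))
            add_edge(drug, "targets", gene)
            if cfg.mechanism_hops == 2:
                add_edge(gene, "associated_with", disease)
                path = KGPath((drug, gene, disease), ("targets", "associated_with"))
            else:
                pw = pw_pool[rng.integers(len(pw_pool))]
                add_edge(gene, "participates_in", pw)
                add_edge(pw, "associated_with", disease)
                path = KGPath(
                    (drug, gene, pw, disease),
                    ("targets", "participates_in", "associated_with"),
                )
            if path not in mechanism_paths:
                mechanism_paths.append(path)
            for a, b in zip(path.nodes, path.nodes[1:]):
                signal_pairs.add((a, b))

    # decoy edges: category-respecting clutter, never drug-disease
    decoy_templates = [
        (drugs, genes, "interacts_with"),
        (genes, genes, "interacts_with"),
        (genes, pathways, "participates_in"),
        (genes, diseases, "associated_with"),
        (pathways, diseases, "associated_with"),
    ]
    n_nodes = len(nodes)
    n_decoys = int(cfg.decoy_edge_rate * n_nodes)
    for _ in range(n_decoys):
        src_pool, dst_pool, pred = decoy_templates[rng.integers(len(decoy_templates))]
        s = src_pool[rng.integers(len(src_pool))]
        o = dst_pool[rng.integers(len(dst_pool))]
        if s != o:
            add_edge(s, pred, o, source="decoy")

    graph = KnowledgeGraph(nodes=nodes, edges=list(edge_set.values()))

    # publication map: per-node background pubs + pair-level shared pubs
    pubs: dict[str, set[str]] = {v: set() for v in nodes}
    pub_counter = 0

    def new_pubs(n: int) -> list[str]:
        nonlocal pub_counter
        out = [f"PMID:{pub_counter + i}" for i in range(n)]
        pub_counter += n
        return out

    for v in sorted(nodes):
        pubs[v].update(new_pubs(cfg.n_background_pubs))
    edge_pairs = sorted({(e.subject, e.object) for e in graph.edges})
    for a, b in edge_pairs:
        lam = (cfg.pub_lambda_signal if (a, b) in signal_pairs
               else cfg.pub_lambda_noise)
        shared = new_pubs(int(rng.poisson(lam)))
        pubs[a].update(shared)
        pubs[b].update(shared)
    # treat pairs also co-occur in the literature (supports the NGD filter)
    for drug, disease in treat_keys:
        shared = new_pubs(int(rng.poisson(cfg.pub_lambda_signal)))
        pubs[drug].update(shared)
        pubs[disease].update(shared)
    pub_map = ConceptPubMap(
        pubs={v: frozenset(s) for v, s in pubs.items()},
        total_pairs=cfg.total_pairs,
    )

    pairs = [LabeledPair(d, z, TREAT) for d, z in treat_keys] + [
        LabeledPair(d, z, NOT_TREAT) for d, z in not_treat_keys
    ]
    truth = GroundTruth(
        treat_pairs=[p for p in pairs if p.label == TREAT],
        not_treat_pairs=[p for p in pairs if p.label == NOT_TREAT],
        mechanism_paths=mechanism_paths,
        drug_targets=sorted(set(drug_targets)),
    )
    return SyntheticFixture(graph=graph, pairs=pairs, pub_map=pub_map, truth=truth)


@dataclass(frozen=True)
class TwoCommunityConfig:
    n_per_community: int = 40
    p_within: float = 0.2
    p_between: float = 0.01
    seed: int = 0


def two_community_graph(cfg: TwoCommunityConfig) -> tuple[KnowledgeGraph, dict[str, int]]:
    """Stochastic-block-model-like fixture: two dense communities, sparse
    cross edges.  Returns the graph and node -> community labels."""
    rng = np.random.default_rng(cfg.seed)
    ids = [f"N:{c}:{i:03d}" for c in (0, 1) for i in range(cfg.n_per_community)]
    labels = {v: int(v.split(":")[1]) for v in ids}
    nodes = {
        v: BioNode(id=v, name=f"node {v}", category="Gene") for v in ids
    }
    edges = []
    for i, u in enumerate(ids):
        for j, v in enumerate(ids):
            if i == j:
                continue
            p = cfg.p_within if labels[u] == labels[v] else cfg.p_between
            if rng.random() < p:
                edges.append(BioEdge(u, "interacts_with", v, source="sbm"))
    graph = KnowledgeGraph(nodes=nodes, edges=edges)
    return graph, labels


def write_fixture(fixture: SyntheticFixture, out_dir: str | Path) -> None:
    """Write all fixture files in the package's text formats."""
    from .demo_paths import save_paths
    from .kg_store import save_graph
    from .literature_ngd import save_concept_pub_map
    from .pair_data import save_pairs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_graph(fixture.graph, out / "nodes.tsv", out / "edges.tsv")
    save_pairs(fixture.pairs, out / "pairs.tsv")
    save_concept_pub_map(fixture.pub_map, out / "concept_pubs.tsv")
    save_paths(fixture.truth.mechanism_paths, out / "mechanism_paths.jsonl")
    with open(out / "drug_targets.tsv", "w") as fh:
        fh.write("drug\ttarget\n")
        for drug, target in fixture.truth.drug_targets:
            fh.write(f"{drug}\t{target}\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(fixture.truth.to_json(), fh, indent=2)
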