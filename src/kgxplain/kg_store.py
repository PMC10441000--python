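"""Directed biomedical knowledge-graph container, loaders and filters.

The graph is a directed multigraph of typed nodes (``id``, ``name``,
``category``) and predicated edges (``subject``, ``predicate``, ``object``,
``source``).  It backs every other component: pair labelling, embeddings,
the RL environment and path scoring all read from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Node categories treated as drugs by default.
DEFAULT_DRUG_CATEGORIES = frozenset({"Drug", "SmallMolecule", "Small Molecule"})

#: Node categories treated as diseases by default.
DEFAULT_DISEASE_CATEGORIES = frozenset(
    {
        "Disease",
        "PhenotypicFeature",
        "BehavioralFeature",
        "DiseaseOrPhenotypicFeature",
    }
)

NODE_COLUMNS = ("id", "name", "category")
EDGE_COLUMNS = ("subject", "predicate", "object", "source")


class GraphFormatError(ValueError):
    """A node/edge table is missing required columns."""


class GraphValidationError(ValueError):
    """Graph content violates an invariant (dangling edge, ambiguous node...)."""


@dataclass(frozen=True)
class BioNode:
    id: str
    name: str
    category: str

    def __post_init__(self) -> None:
        if not self.category:
            raise GraphValidationError(f"node {self.id!r} has empty category")


@dataclass(frozen=True)
class BioEdge:
    subject: str
    predicate: str
    object: str
    source: str = ""
    provenance_count: int = 1

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject, self.predicate, self.object)


@dataclass
class KnowledgeGraph:
    """Directed multigraph with drug/disease category designations."""

    nodes: dict[str, BioNode]
    edges: list[BioEdge]
    drug_categories: frozenset[str] = DEFAULT_DRUG_CATEGORIES
    disease_categories: frozenset[str] = DEFAULT_DISEASE_CATEGORIES
    _out: dict[str, list[tuple[str, str]]] = field(default_factory=dict, repr=False)
    _in: dict[str, list[tuple[str, str]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise GraphValidationError("graph must contain at least one node")
        for e in self.edges:
            if e.subject not in self.nodes or e.object not in self.nodes:
                raise GraphValidationError(
                    f"edge ({e.subject}, {e.predicate}, {e.object}) references "
                    "an unknown node"
                )
        overlap = self.drug_ids() & self.disease_ids()
        if overlap:
            raise GraphValidationError(
                f"nodes in both drug and disease categories: {sorted(overlap)[:5]}"
            )
        self._rebuild_adjacency()

    def _rebuild_adjacency(self) -> None:
        out: dict[str, list[tuple[str, str]]] = {v: [] for v in self.nodes}
        inc: dict[str, list[tuple[str, str]]] = {v: [] for v in self.nodes}
        for e in self.edges:
            out[e.subject].append((e.predicate, e.object))
            inc[e.object].append((e.predicate, e.subject))
        for v in out:
            out[v].sort()
            inc[v].sort()
        self._out = out
        self._in = inc

    # -- queries ---------------------------------------------------------

    def drug_ids(self) -> set[str]:
        return {v for v, n in self.nodes.items() if n.category in self.drug_categories}

    def disease_ids(self) -> set[str]:
        return {
            v for v, n in self.nodes.items() if n.category in self.disease_categories
        }

    def out_edges(self, v: str) -> list[tuple[str, str]]:
        """Sorted (predicate, neighbor) list; parallel edges give distinct entries."""
        try:
            return list(self._out[v])
        except KeyError:
            raise KeyError(f"unknown node {v!r}") from None

    def in_edges(self, v: str) -> list[tuple[str, str]]:
        try:
            return list(self._in[v])
        except KeyError:
            raise KeyError(f"unknown node {v!r}") from None

    def neighbors(self, v: str) -> list[str]:
        """Sorted union of in- and out-neighbors (for aggregation)."""
        return sorted({u for _, u in self._out[v]} | {u for _, u in self._in[v]})

    def has_edge(self, subject: str, predicate: str, obj: str) -> bool:
        return (predicate, obj) in self._out.get(subject, ())

    def category_of(self, v: str) -> str:
        return self.nodes[v].category

    def predicates(self) -> list[str]:
        return sorted({e.predicate for e in self.edges})

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for v, n in self.nodes.items():
            g.add_node(v, name=n.name, category=n.category)
        for e in self.edges:
            g.add_edge(e.subject, e.object, predicate=e.predicate, source=e.source)
        return g


@dataclass
class KGFilterConfig:
    """Configurable stand-ins for the graph customization steps."""

    excluded_categories: frozenset[str] = frozenset()
    low_quality_sources: frozenset[str] = frozenset()
    min_provenance_count: int = 0
    predicate_hierarchy: dict[str, str] | None = None
    drop_drug_disease_edges: bool = True

    def validate(self, g: KnowledgeGraph) -> None:
        if self.min_provenance_count < 0:
            raise ValueError("min_provenance_count must be >= 0")
        if self.drop_drug_disease_edges:
            protected = g.drug_categories | g.disease_categories
            clash = self.excluded_categories & protected
            if clash:
                raise ValueError(
                    "excluded_categories would remove drug/disease nodes: "
                    f"{sorted(clash)}"
                )


def load_graph(
    node_table: str,
    edge_table: str,
    drug_categories: frozenset[str] = DEFAULT_DRUG_CATEGORIES,
    disease_categories: frozenset[str] = DEFAULT_DISEASE_CATEGORIES,
) -> KnowledgeGraph:
    """Load a graph from TSV node/edge tables.

    Exact duplicate (subject, predicate, object) rows collapse to a single
    edge keeping the first-seen source tag.
    """
    nodes_df = pd.read_csv(node_table, sep="\t", dtype=str)
    missing = set(NODE_COLUMNS) - set(nodes_df.columns)
    if missing:
        raise GraphFormatError(f"node table missing columns: {sorted(missing)}")
    edges_df = pd.read_csv(edge_table, sep="\t", dtype=str)
    required = set(EDGE_COLUMNS) - {"source"}
    missing = required - set(edges_df.columns)
    if missing:
        raise GraphFormatError(f"edge table missing columns: {sorted(missing)}")
    if "source" not in edges_df.columns:
        edges_df["source"] = ""
    if "provenance_count" not in edges_df.columns:
        edges_df["provenance_count"] = "1"

    nodes: dict[str, BioNode] = {}
    for row in nodes_df.itertuples(index=False):
        node = BioNode(id=row.id, name=str(row.name), category=row.category)
        if node.id in nodes:
            raise GraphValidationError(f"duplicate node id {node.id!r}")
        nodes[node.id] = node

    seen: set[tuple[str, str, str]] = set()
    edges: list[BioEdge] = []
    for row in edges_df.itertuples(index=False):
        edge = BioEdge(
            subject=row.subject,
            predicate=row.predicate,
            object=row.object,
            source="" if pd.isna(row.source) else str(row.source),
            provenance_count=int(float(row.provenance_count)),
        )
        if edge.key in seen:
            continue
        seen.add(edge.key)
        edges.append(edge)

    g = KnowledgeGraph(
        nodes=nodes,
        edges=edges,
        drug_categories=drug_categories,
        disease_categories=disease_categories,
    )
    logger.info("loaded graph: %d nodes, %d edges", len(g.nodes), len(g.edges))
    return g


def save_graph(g: KnowledgeGraph, node_table: str, edge_table: str) -> None:
    pd.DataFrame(
        [(n.id, n.name, n.category) for n in g.nodes.values()],
        columns=list(NODE_COLUMNS),
    ).to_csv(node_table, sep="\t", index=False)
    pd.DataFrame(
        [
            (e.subject, e.predicate, e.object, e.source, e.provenance_count)
            for e in g.edges
        ],
        columns=list(EDGE_COLUMNS) + ["provenance_count"],
    ).to_csv(edge_table, sep="\t", index=False)


def customize_graph(g: KnowledgeGraph, cfg: KGFilterConfig) -> KnowledgeGraph:
    """Apply the four customization filters, returning a new graph.

    Order: category exclusion, low-quality edge removal, hierarchical
    redundancy removal, drug-disease edge removal.  Counts after each step
    are logged; the operation is idempotent.
    """
    cfg.validate(g)

    nodes = {
        v: n for v, n in g.nodes.items() if n.category not in cfg.excluded_categories
    }
    edges = [e for e in g.edges if e.subject in nodes and e.object in nodes]
    logger.info("after category filter: %d nodes, %d edges", len(nodes), len(edges))

    edges = [
        e
        for e in edges
        if e.source not in cfg.low_quality_sources
        and e.provenance_count >= cfg.min_provenance_count
    ]
    logger.info("after low-quality filter: %d edges", len(edges))

    if cfg.predicate_hierarchy:
        ancestors: dict[str, set[str]] = {}
        for child in cfg.predicate_hierarchy:
            chain: set[str] = set()
            p = child
            while p in cfg.predicate_hierarchy and cfg.predicate_hierarchy[p] not in chain:
                p = cfg.predicate_hierarchy[p]
                chain.add(p)
            ancestors[child] = chain
        by_pair: dict[tuple[str, str], set[str]] = {}
        for e in edges:
            by_pair.setdefault((e.subject, e.object), set()).add(e.predicate)
        redundant: set[tuple[str, str, str]] = set()
        for (s, o), preds in by_pair.items():
            for child in preds:
                for anc in ancestors.get(child, ()):
                    if anc in preds:
                        redundant.add((s, anc, o))
        edges = [e for e in edges if e.key not in redundant]
        logger.info("after hierarchy filter: %d edges", len(edges))

    if cfg.drop_drug_disease_edges:
        drugs = {
            v for v, n in nodes.items() if n.category in g.drug_categories
        }
        diseases = {
            v for v, n in nodes.items() if n.category in g.disease_categories
        }
        edges = [
            e
            for e in edges
            if not (
                (e.subject in drugs and e.object in diseases)
                or (e.subject in diseases and e.object in drugs)
            )
        ]
        logger.info("after drug-disease edge filter: %d edges", len(edges))

    return KnowledgeGraph(
        nodes=nodes,
        edges=edges,
        drug_categories=g.drug_categories,
        disease_categories=g.disease_categories,
    )


def node_sets(g: KnowledgeGraph) -> tuple[set[str], set[str]]:
    """Return (drug ids, disease ids) per the graph's category designations."""
    return g.drug_ids(), g.disease_ids()


def pagerank_scores(g: KnowledgeGraph, alpha: float = 0.85) -> dict[str, float]:
    """PageRank on the directed graph (damping 0.85); scores sum to 1."""
    nxg = nx.DiGraph()
    nxg.add_nodes_from(g.nodes)
    nxg.add_edges_from((e.subject, e.object) for e in g.edges)
    return nx.pagerank(nxg, alpha=alpha, tol=1e-12, max_iter=500)
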