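"""Demonstration-path extraction: biologically plausible drug->...->disease
paths anchored at known drug targets, ranked by literature closeness."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .kg_store import KnowledgeGraph
from .literature_ngd import ConceptPubMap, ngd


@dataclass(frozen=True)
class KGPath:
    nodes: tuple[str, ...]
    predicates: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.predicates) + 1:
            raise ValueError("path needs exactly one more node than predicates")
        if not self.predicates:
            raise ValueError("path must have at least one hop")

    @property
    def hops(self) -> int:
        return len(self.predicates)

    def validate(self, g: KnowledgeGraph) -> None:
        for i, pred in enumerate(self.predicates):
            if not g.has_edge(self.nodes[i], pred, self.nodes[i + 1]):
                raise ValueError(
                    f"edge ({self.nodes[i]}, {pred}, {self.nodes[i + 1]}) "
                    "not present in graph"
                )


@dataclass(frozen=True)
class MetaPath:
    categories: tuple[str, ...]


def _mean_consecutive_ngd(path: KGPath, pub_map: ConceptPubMap | None) -> float:
    """Mean NGD over consecutive node pairs; missing info scores worst (+inf)."""
    if pub_map is None:
        return math.inf
    total = 0.0
    for a, b in zip(path.nodes, path.nodes[1:]):
        if pub_map.count(a) == 0 or pub_map.count(b) == 0:
            return math.inf
        d = ngd(pub_map, a, b)
        if math.isinf(d):
            return math.inf
        total += d
    return total / path.hops


def extract_demonstration_paths(
    g: KnowledgeGraph,
    treat_pairs: list,
    drug_targets: list[tuple[str, str]],
    pub_map: ConceptPubMap | None = None,
    max_hops: int = 3,
    per_pair_cap: int = 50,
) -> list[KGPath]:
    """Enumerate drug->...->disease paths (length <= max_hops) whose second
    node is a known target of the drug; keep the per-pair cap-best by mean
    consecutive-node NGD (ties by lexicographic node sequence)."""
    targets_by_drug: dict[str, set[str]] = {}
    for drug, target in drug_targets:
        targets_by_drug.setdefault(drug, set()).add(target)

    out: list[KGPath] = []
    seen: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    for pair in treat_pairs:
        drug, disease = pair.drug, pair.disease
        if drug not in g.nodes or disease not in g.nodes:
            continue
        targets = targets_by_drug.get(drug, set())
        if not targets:
            continue
        found: list[KGPath] = []
        # depth-first over simple paths, first hop restricted to targets
        stack: list[tuple[list[str], list[str]]] = []
        for pred, nbr in g.out_edges(drug):
            if nbr in targets:
                stack.append(([drug, nbr], [pred]))
        while stack:
            nodes, preds = stack.pop()
            cur = nodes[-1]
            if cur == disease:
                found.append(KGPath(tuple(nodes), tuple(preds)))
                continue
            if len(preds) >= max_hops:
                continue
            for pred, nbr in g.out_edges(cur):
                if nbr in nodes:
                    continue
                stack.append((nodes + [nbr], preds + [pred]))
        found.sort(key=lambda p: (_mean_consecutive_ngd(p, pub_map), p.nodes))
        for path in found[:per_pair_cap]:
            key = (path.nodes, path.predicates)
            if key not in seen:
                seen.add(key)
                out.append(path)
    return out


def demo_metapaths(
    g: KnowledgeGraph, paths: list[KGPath]
) -> dict[MetaPath, int]:
    """Map paths to category sequences, keeping multiplicities."""
    counts: dict[MetaPath, int] = {}
    for p in paths:
        mp = MetaPath(tuple(g.category_of(v) for v in p.nodes))
        counts[mp] = counts.get(mp, 0) + 1
    return counts


# -- I/O -----------------------------------------------------------------

def save_paths(paths: list[KGPath], path: str) -> None:
    with open(path, "w") as fh:
        for p in paths:
            fh.write(json.dumps({"nodes": list(p.nodes),
                                 "predicates": list(p.predicates)}) + "\n")


def load_paths(path: str) -> list[KGPath]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(KGPath(tuple(rec["nodes"]), tuple(rec["predicates"])))
    return out


def load_drug_targets(path: str) -> list[tuple[str, str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [(r.drug, r.target) for r in df.itertuples(index=False)]
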