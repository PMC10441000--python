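"""Publication-co-occurrence normalized Google distance and the literature filter."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


class NGDDomainError(ValueError):
    """NGD is undefined for a concept with zero publications."""


@dataclass
class ConceptPubMap:
    """Concept -> set of publication ids, plus the corpus-level normalizer N."""

    pubs: dict[str, frozenset[str]]
    total_pairs: int

    def __post_init__(self) -> None:
        if self.total_pairs <= 0:
            raise ValueError("total_pairs must be positive")
        biggest = max((len(p) for p in self.pubs.values()), default=0)
        if self.total_pairs < biggest:
            raise ValueError(
                "total_pairs must be at least the largest single-concept count"
            )

    def count(self, c: str) -> int:
        return len(self.pubs.get(c, ()))

    def cooccurrence(self, c1: str, c2: str) -> int:
        a = self.pubs.get(c1)
        b = self.pubs.get(c2)
        if not a or not b:
            return 0
        return len(a & b)


def load_concept_pub_map(path: str) -> ConceptPubMap:
    """Read a long-format ``concept_id<TAB>publication_id`` TSV.

    A leading comment line ``#total_pairs=N`` supplies the normalizer.
    """
    total_pairs = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#total_pairs="):
            total_pairs = int(first.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t", dtype=str)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype=str)
    if total_pairs is None:
        raise ValueError(f"{path}: missing '#total_pairs=N' header comment")
    pubs: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        pubs.setdefault(row.concept_id, set()).add(row.publication_id)
    return ConceptPubMap(
        pubs={c: frozenset(s) for c, s in pubs.items()}, total_pairs=total_pairs
    )


def save_concept_pub_map(m: ConceptPubMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#total_pairs={m.total_pairs}\n")
        fh.write("concept_id\tpublication_id\n")
        for c in sorted(m.pubs):
            for p in sorted(m.pubs[c]):
                fh.write(f"{c}\t{p}\n")


def ngd(m: ConceptPubMap, c1: str, c2: str, base: float = math.e) -> float:
    """Normalized Google distance between two concepts.

    ``(max(log n1, log n2) - log n12) / (log N - min(log n1, log n2))``.
    The ratio of log-differences makes the logarithm base irrelevant.
    Zero co-occurrence returns +inf; a concept with zero publications is a
    domain error.
    """
    n1 = m.count(c1)
    n2 = m.count(c2)
    if n1 == 0 or n2 == 0:
        raise NGDDomainError(
            f"NGD undefined: concept with zero publications among ({c1!r}, {c2!r})"
        )
    n12 = m.cooccurrence(c1, c2)
    if n12 == 0:
        return math.inf
    log = lambda x: math.log(x, base)  # noqa: E731
    num = max(log(n1), log(n2)) - log(n12)
    den = log(m.total_pairs) - min(log(n1), log(n2))
    return num / den


@dataclass
class FilterAudit:
    drug: str
    disease: str
    cooccurrence: int
    ngd: float
    kept: bool


def literature_filter(
    m: ConceptPubMap,
    pairs: list,
    min_cooccur: int = 10,
    max_ngd: float = 0.6,
    audit: list[FilterAudit] | None = None,
) -> list:
    """Keep pairs with co-occurrence >= min_cooccur AND NGD <= max_ngd.

    Both boundaries inclusive.  Endpoints absent from the map count as zero
    co-occurrence (dropped).  ``pairs`` items need ``drug``/``disease``
    attributes; the output preserves input order.
    """
    kept = []
    for p in pairs:
        co = m.cooccurrence(p.drug, p.disease)
        if co == 0 or m.count(p.drug) == 0 or m.count(p.disease) == 0:
            score = math.inf
        else:
            score = ngd(m, p.drug, p.disease)
        ok = co >= min_cooccur and score <= max_ngd
        if audit is not None:
            audit.append(FilterAudit(p.drug, p.disease, co, score, ok))
        if ok:
            kept.append(p)
    return kept
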