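"""Drug-repurposing prediction: pair features, 3-class random-forest
classifier, treat-probability prediction, and replacement-candidate ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .node_embeddings import EmbeddingTable
from .pair_data import LabeledPair, NOT_TREAT, TREAT, UNKNOWN

logger = logging.getLogger(__name__)

CLASS_ORDER = (NOT_TREAT, TREAT, UNKNOWN)


@dataclass
class PairFeature:
    drug: str
    disease: str
    vector: np.ndarray  # drug embedding ++ disease embedding, drug first
    label: str | None = None


@dataclass
class DRPModel:
    classifier: RandomForestClassifier
    classes: tuple[str, ...]
    feature_dim: int
    seed: int

    @property
    def treat_index(self) -> int:
        return self.classes.index(TREAT)


class CandidatePoolError(ValueError):
    pass


def pair_features(
    emb: EmbeddingTable, pairs: list[LabeledPair]
) -> list[PairFeature]:
    """Concatenate drug then disease embedding for every pair."""
    out = []
    for p in pairs:
        for node in (p.drug, p.disease):
            if node not in emb:
                raise KeyError(f"no embedding for node {node!r}")
        out.append(
            PairFeature(
                drug=p.drug,
                disease=p.disease,
                vector=np.concatenate([emb[p.drug], emb[p.disease]]),
                label=p.label,
            )
        )
    return out


def _design(features: list[PairFeature]) -> np.ndarray:
    return np.stack([f.vector for f in features])


def fit_drp(
    features: list[PairFeature],
    seed: int = 0,
    n_estimators: int = 1000,
    max_depth: int | None = None,
    two_class: bool = False,
) -> DRPModel:
    """Fit the tree-ensemble pair classifier.

    ``two_class`` drops the unknown class (ablation mode); otherwise all
    three labels must be present in the training data.
    """
    required = {NOT_TREAT, TREAT} if two_class else set(CLASS_ORDER)
    present = {f.label for f in features}
    missing = required - present
    if missing:
        raise ValueError(f"training data missing classes: {sorted(missing)}")
    if two_class:
        features = [f for f in features if f.label != UNKNOWN]
    x = _design(features)
    y = np.array([f.label for f in features])
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(x, y)
    acc = float(clf.score(x, y))
    logger.info("DRP training accuracy: %.4f", acc)
    return DRPModel(
        classifier=clf,
        classes=tuple(clf.classes_),
        feature_dim=x.shape[1],
        seed=seed,
    )


def predict_treat_proba(
    m: DRPModel, features: list[PairFeature]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair class probabilities (columns in ``m.classes`` order) and p_treat."""
    if not features:
        return np.zeros((0, len(m.classes))), np.zeros(0)
    x = _design(features)
    if x.shape[1] != m.feature_dim:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match model dim {m.feature_dim}"
        )
    proba = m.classifier.predict_proba(x)
    return proba, proba[:, m.treat_index]


def predicted_labels(m: DRPModel, features: list[PairFeature]) -> np.ndarray:
    proba, _ = predict_treat_proba(m, features)
    return np.array([m.classes[i] for i in proba.argmax(axis=1)])


@dataclass(frozen=True)
class ReplacementProtocol:
    mode: str = "random_subset"  # drug | disease | combined | random_subset
    subset_size: int = 1000
    per_side: int = 500
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("drug", "disease", "combined", "random_subset"):
            raise ValueError(f"unknown replacement mode {self.mode!r}")
        if self.mode == "random_subset" and 2 * self.per_side != self.subset_size:
            raise ValueError("random_subset requires 2 * per_side == subset_size")


def generate_replacement_candidates(
    pair: LabeledPair,
    protocol: ReplacementProtocol,
    known_positives: set[tuple[str, str]],
    drug_ids: set[str],
    disease_ids: set[str],
) -> list[list[tuple[str, str]]]:
    """Candidate non-positive pairs for one true-positive query.

    Returns one candidate list per repeat (a single list for the exhaustive
    modes).  Candidates never include known positives or the query pair.
    """
    query = (pair.drug, pair.disease)
    drug_side = [
        (d, pair.disease)
        for d in sorted(drug_ids)
        if d != pair.drug and (d, pair.disease) not in known_positives
    ]
    disease_side = [
        (pair.drug, z)
        for z in sorted(disease_ids)
        if z != pair.disease and (pair.drug, z) not in known_positives
    ]
    drug_side = [c for c in drug_side if c != query]
    disease_side = [c for c in disease_side if c != query]

    if protocol.mode == "drug":
        return [drug_side]
    if protocol.mode == "disease":
        return [disease_side]
    if protocol.mode == "combined":
        return [sorted(set(drug_side) | set(disease_side))]

    if len(drug_side) < protocol.per_side or len(disease_side) < protocol.per_side:
        raise CandidatePoolError(
            f"pools too small for per_side={protocol.per_side}: "
            f"{len(drug_side)} drug-replacements, {len(disease_side)} "
            "disease-replacements"
        )
    rng = np.random.default_rng(protocol.seed)
    repeats = []
    for _ in range(protocol.repeats):
        di = rng.choice(len(drug_side), size=protocol.per_side, replace=False)
        zi = rng.choice(len(disease_side), size=protocol.per_side, replace=False)
        repeats.append([drug_side[i] for i in di] + [disease_side[i] for i in zi])
    return repeats


def _competition_rank(
    query: tuple[str, str],
    query_score: float,
    candidates: list[tuple[str, str]],
    scores: np.ndarray,
) -> int:
    """Rank = 1 + #candidates strictly better; equal scores break by
    lexicographic (drug, disease) order."""
    better = 0
    for cand, s in zip(candidates, scores):
        if s > query_score or (s == query_score and cand < query):
            better += 1
    return better + 1


@dataclass
class RankRecord:
    drug: str
    disease: str
    repeat: int
    rank: int
    n_candidates: int  # includes the query itself


def rank_true_positives(
    m: DRPModel,
    positives: list[LabeledPair],
    protocol: ReplacementProtocol,
    emb: EmbeddingTable,
    known_positives: set[tuple[str, str]],
    drug_ids: set[str],
    disease_ids: set[str],
    batch_size: int = 8192,
) -> list[RankRecord]:
    """Rank each positive among itself + replacement candidates by p_treat."""
    records: list[RankRecord] = []
    for pair in positives:
        repeats = generate_replacement_candidates(
            pair, protocol, known_positives, drug_ids, disease_ids
        )
        (_, q_treat) = predict_treat_proba(
            m, pair_features(emb, [pair])
        )
        q_score = float(q_treat[0])
        for rep_i, candidates in enumerate(repeats):
            scores = np.empty(len(candidates))
            for lo in range(0, len(candidates), batch_size):
                chunk = candidates[lo:lo + batch_size]
                feats = pair_features(
                    emb, [LabeledPair(d, z, UNKNOWN) for d, z in chunk]
                )
                _, p_treat = predict_treat_proba(m, feats)
                scores[lo:lo + len(chunk)] = p_treat
            rank = _competition_rank(
                (pair.drug, pair.disease), q_score, candidates, scores
            )
            records.append(
                RankRecord(
                    drug=pair.drug,
                    disease=pair.disease,
                    repeat=rep_i,
                    rank=rank,
                    n_candidates=len(candidates) + 1,
                )
            )
    return records
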