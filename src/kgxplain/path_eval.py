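"""Path enumeration, policy-based path scoring, curated-path matching, and
classification / ranking metrics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

from .demo_paths import KGPath
from .kg_store import KnowledgeGraph
from .moa_rl import Action, MOAAgent
from .pair_data import UNKNOWN


@dataclass(frozen=True)
class ScoredPath:
    path: KGPath
    score: float
    rank: int = 0
    n_candidates: int = 0


@dataclass
class MetricReport:
    acc: float | None = None
    macro_f1: float | None = None
    mpr: float | None = None
    mrr: float | None = None
    hit_at_k: dict[int, float] | None = None


def enumerate_paths(
    g: KnowledgeGraph, drug: str, disease: str, max_hops: int = 3,
    exact: bool = True,
) -> list[KGPath]:
    """Directed simple paths drug -> disease with exactly ``max_hops`` edges
    (or up to ``max_hops`` when ``exact`` is false), in deterministic order."""
    for v in (drug, disease):
        if v not in g.nodes:
            raise KeyError(f"unknown node {v!r}")
    out: list[KGPath] = []
    stack = [([drug], [])]
    while stack:
        nodes, preds = stack.pop()
        cur = nodes[-1]
        if cur == disease and preds and (not exact or len(preds) == max_hops):
            out.append(KGPath(tuple(nodes), tuple(preds)))
            continue
        if len(preds) >= max_hops or cur == disease:
            continue
        for pred, nbr in g.out_edges(cur):
            if nbr in nodes:
                continue
            if nbr != disease and len(preds) == max_hops - 1:
                continue
            stack.append((nodes + [nbr], preds + [pred]))
    out.sort(key=lambda p: (p.nodes, p.predicates))
    return out


def score_path(agent: MOAAgent, path: KGPath, delta: float = 0.9) -> float:
    """sum_i delta^(i-1) * log(P_i * N_i) along the path under the policy.

    P_i is the policy probability of the path's i-th action in the
    reconstructed state; N_i is the size of the (pruned) action space
    including the self-loop.  P_i == 0 (e.g., an action pruned out of the
    action space) gives -inf.
    """
    ctx = agent.ctx
    state = ctx.initial_state(path.nodes[0])
    score = 0.0
    for i, (pred, nxt) in enumerate(zip(path.predicates, path.nodes[1:])):
        space = ctx.action_space(state)
        action = Action(pred, nxt)
        try:
            idx = space.index(action)
        except ValueError:
            return -math.inf
        probs = agent.action_probs(state, space)
        p_i = float(probs[idx])
        n_i = len(space)
        if p_i <= 0.0:
            return -math.inf
        score += delta**i * math.log(p_i * n_i)
        state = ctx.env_step(state, action)
    return score


def score_paths(agent: MOAAgent, paths: list[KGPath],
                delta: float = 0.9) -> list[ScoredPath]:
    """Score many paths, memoizing policy distributions per visited state
    (candidate paths of one pair share long prefixes)."""
    ctx = agent.ctx
    memo: dict[tuple, tuple[dict, int]] = {}
    out = []
    for path in paths:
        state = ctx.initial_state(path.nodes[0])
        score = 0.0
        for i, (pred, nxt) in enumerate(zip(path.predicates, path.nodes[1:])):
            key = state.key()
            cached = memo.get(key)
            if cached is None:
                space = ctx.action_space(state)
                probs = agent.action_probs(state, space)
                lookup = {(a.predicate, a.next): float(p)
                          for a, p in zip(space, probs)}
                cached = (lookup, len(space))
                memo[key] = cached
            lookup, n_i = cached
            p_i = lookup.get((pred, nxt), 0.0)
            if p_i <= 0.0:
                score = -math.inf
                break
            score += delta**i * math.log(p_i * n_i)
            state = ctx.env_step(state, Action(pred, nxt))
        out.append(ScoredPath(path, score))
    return out


def rank_paths(scored: list[ScoredPath]) -> list[ScoredPath]:
    """Competition ranking by descending score, ties broken by node sequence."""
    if not scored:
        raise ValueError("need at least one path to rank")
    order = sorted(scored, key=lambda s: (-s.score, s.path.nodes, s.path.predicates))
    n = len(order)
    out = []
    for i, sp in enumerate(order):
        rank = 1 + sum(1 for other in scored if other.score > sp.score)
        # ties: stable position among equals via the sorted order
        rank = rank + sum(
            1
            for other in order[:i]
            if other.score == sp.score
        )
        out.append(ScoredPath(sp.path, sp.score, rank=rank, n_candidates=n))
    return out


def match_curated(path: KGPath, curated: list[str]) -> bool:
    """True iff every node of the path appears in the curated node sequence."""
    pool = set(curated)
    return all(v in pool for v in path.nodes)


def best_matched_rank(
    ranked: list[ScoredPath], curated_paths: list[list[str]]
) -> int | None:
    """Smallest rank among paths matching any curated path, or None."""
    best = None
    for sp in ranked:
        if any(match_curated(sp.path, cur) for cur in curated_paths):
            if best is None or sp.rank < best:
                best = sp.rank
    return best


def ranking_metrics(
    ranks: list[int],
    n_candidates: list[int],
    k_list: tuple[int, ...] = (1, 3, 5),
) -> MetricReport:
    """MRR = mean(1/r); Hit@K = mean(r <= K); MPR = mean(100 (n - r + 1) / n)."""
    if not ranks:
        raise ValueError("empty rank list")
    if len(ranks) != len(n_candidates):
        raise ValueError("ranks and n_candidates must align")
    for r, n in zip(ranks, n_candidates):
        if r < 1 or r > n:
            raise ValueError(f"rank {r} outside [1, {n}]")
    ranks_arr = np.asarray(ranks, dtype=np.float64)
    n_arr = np.asarray(n_candidates, dtype=np.float64)
    return MetricReport(
        mrr=float(np.mean(1.0 / ranks_arr)),
        mpr=float(np.mean(100.0 * (n_arr - ranks_arr + 1.0) / n_arr)),
        hit_at_k={k: float(np.mean(ranks_arr <= k)) for k in k_list},
    )


def classification_metrics(
    y_true: list[str],
    y_pred: list[str],
    classes: tuple[str, ...],
    exclude_unknown: bool = False,
) -> MetricReport:
    """Accuracy and unweighted macro-F1.

    With ``exclude_unknown``, pairs whose true label is unknown are dropped
    and F1 is averaged over the remaining classes.  A class absent from both
    truth and prediction contributes F1 = 0 with a warning.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label lists must align")
    labels = list(classes)
    if exclude_unknown:
        keep = [i for i, t in enumerate(y_true) if t != UNKNOWN]
        y_true = [y_true[i] for i in keep]
        y_pred = [y_pred[i] for i in keep]
        labels = [c for c in labels if c != UNKNOWN]
    for c in labels:
        if c not in y_true and c not in y_pred:
            warnings.warn(
                f"class {c!r} has no true or predicted members; F1 set to 0",
                stacklevel=2,
            )
    acc = float(accuracy_score(y_true, y_pred))
    f1 = float(f1_score(y_true, y_pred, labels=labels, average="macro",
                        zero_division=0))
    return MetricReport(acc=acc, macro_f1=f1)
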