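import math
import warnings

import networkx as nx
import numpy as np
import pytest

from kgxplain.demo_paths import KGPath
from kgxplain.path_eval import (
    ScoredPath,
    best_matched_rank,
    classification_metrics,
    enumerate_paths,
    match_curated,
    rank_paths,
    ranking_metrics,
    score_path,
)

from conftest import make_graph


class TestEnumerate:
    def diamond(self):
        return make_graph(
            [("d", "Drug"), ("a", "Gene"), ("b", "Gene"), ("c", "Pathway"),
             ("e", "Pathway"), ("z", "Disease")],
            [("d", "p", "a"), ("d", "p", "b"),
             ("a", "q", "c"), ("b", "q", "c"), ("a", "q", "e"),
             ("c", "r", "z"), ("e", "r", "z")],
        )

    def test_matches_networkx_oracle(self):
        g = self.diamond()
        got = enumerate_paths(g, "d", "z", max_hops=3)
        nxg = g.to_networkx()
        oracle = {
            tuple(p) for p in nx.all_simple_paths(nxg, "d", "z", cutoff=3)
            if len(p) == 4
        }
        assert {p.nodes for p in got} == oracle
        assert len(got) == 3  # d-a-c-z, d-a-e-z, d-b-c-z

    def test_parallel_edges_give_distinct_paths(self):
        g = make_graph(
            [("d", "Drug"), ("g", "Gene"), ("z", "Disease")],
            [("d", "p1", "g"), ("d", "p2", "g"), ("g", "q", "z")],
        )
        got = enumerate_paths(g, "d", "z", max_hops=2)
        assert len(got) == 2
        assert {p.predicates for p in got} == {("p1", "q"), ("p2", "q")}

    def test_disconnected_pair_empty(self):
        g = make_graph([("d", "Drug"), ("z", "Disease")], [])
        assert enumerate_paths(g, "d", "z") == []

    def test_no_node_revisit(self):
        g = make_graph(
            [("d", "Drug"), ("g", "Gene"), ("z", "Disease")],
            [("d", "p", "g"), ("g", "p", "d"), ("g", "q", "z"), ("d", "r", "z")],
        )
        for p in enumerate_paths(g, "d", "z", max_hops=3):
            assert len(set(p.nodes)) == len(p.nodes)

    def test_deterministic_order(self):
        g = self.diamond()
        assert enumerate_paths(g, "d", "z") == enumerate_paths(g, "d", "z")


class _StubCtx:
    """Fixed action-space sizes; states are hop indices."""

    def __init__(self, path, sizes):
        self.path = path
        self.sizes = sizes

    def initial_state(self, drug):
        return 0

    def action_space(self, state):
        from kgxplain.moa_rl import Action

        n = self.sizes[state]
        real = Action(self.path.predicates[state], self.path.nodes[state + 1])
        return [real] + [Action(f"pad{i}", f"pad{i}") for i in range(n - 1)]

    def env_step(self, state, action):
        return state + 1


class _StubAgent:
    def __init__(self, path, probs, sizes):
        self.ctx = _StubCtx(path, sizes)
        self.probs = probs

    def action_probs(self, state, actions):
        p = np.full(len(actions), (1 - self.probs[state]) / max(len(actions) - 1, 1))
        p[0] = self.probs[state]
        return p


class TestScorePath:
    def test_single_hop_certain_action(self):
        path = KGPath(("d", "z"), ("p",))
        agent = _StubAgent(path, probs=[1.0], sizes=[1])
        assert score_path(agent, path) == pytest.approx(0.0)

    def test_two_hop_half_half(self):
        path = KGPath(("d", "g", "z"), ("p", "q"))
        agent = _StubAgent(path, probs=[0.5, 0.5], sizes=[2, 2])
        # log(0.5*2) + 0.9 log(0.5*2) = 0
        assert score_path(agent, path) == pytest.approx(0.0)

    def test_hand_value_with_decay(self):
        path = KGPath(("d", "g", "z"), ("p", "q"))
        agent = _StubAgent(path, probs=[0.8, 0.4], sizes=[4, 5])
        expected = math.log(0.8 * 4) + 0.9 * math.log(0.4 * 5)
        assert score_path(agent, path) == pytest.approx(expected)

    def test_monotone_in_probability(self):
        path = KGPath(("d", "g", "z"), ("p", "q"))
        low = _StubAgent(path, probs=[0.3, 0.5], sizes=[3, 3])
        high = _StubAgent(path, probs=[0.6, 0.5], sizes=[3, 3])
        assert score_path(high, path) > score_path(low, path)

    def test_zero_probability_minus_inf(self):
        path = KGPath(("d", "g", "z"), ("p", "q"))
        agent = _StubAgent(path, probs=[0.0, 0.5], sizes=[2, 2])
        assert score_path(agent, path) == -math.inf

    def test_real_agent_scores_are_finite(self, small_fixture,
                                          small_fixture_embeddings):
        from kgxplain.moa_rl import MOAAgent, MOAConfig, MOAContext

        attr, _ = small_fixture_embeddings
        ctx = MOAContext(small_fixture.graph, attr,
                         MOAConfig(seed=0, emb_dim=8, hidden_dim=16))
        agent = MOAAgent(ctx)
        mp = small_fixture.truth.mechanism_paths[0]
        assert math.isfinite(score_path(agent, mp))


class TestRankPaths:
    def path(self, tag):
        return KGPath((f"a{tag}", f"b{tag}"), ("p",))

    def test_descending_scores(self):
        scored = [ScoredPath(self.path(i), s) for i, s in enumerate([3.0, 1.0, 2.0])]
        ranks = {sp.score: sp.rank for sp in rank_paths(scored)}
        assert ranks == {3.0: 1, 1.0: 3, 2.0: 2}

    def test_tie_break_by_node_sequence(self):
        scored = [ScoredPath(self.path("x"), 1.0), ScoredPath(self.path("a"), 1.0)]
        out = rank_paths(scored)
        by_tag = {sp.path.nodes[0]: sp.rank for sp in out}
        assert by_tag == {"aa": 1, "ax": 2}

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(0)
        scored = [ScoredPath(self.path(i), float(rng.integers(0, 3)))
                  for i in range(12)]
        out = rank_paths(scored)
        assert sorted(sp.rank for sp in out) == list(range(1, 13))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_paths([])


class TestMatchCurated:
    def test_all_nodes_present(self):
        p = KGPath(("d", "g", "pw", "z"), ("a", "b", "c"))
        assert match_curated(p, ["z", "g", "d", "extra", "pw"])

    def test_one_node_absent(self):
        p = KGPath(("d", "g", "pw", "z"), ("a", "b", "c"))
        assert not match_curated(p, ["d", "g", "z"])

    def test_best_rank_is_min_over_matches(self):
        paths = [
            ScoredPath(KGPath(("d", "g1", "z"), ("p", "q")), 0.0, rank=5, n_candidates=9),
            ScoredPath(KGPath(("d", "g2", "z"), ("p", "q")), 0.0, rank=2, n_candidates=9),
            ScoredPath(KGPath(("d", "g3", "z"), ("p", "q")), 0.0, rank=1, n_candidates=9),
        ]
        curated = [["d", "g1", "z"], ["d", "g2", "z"]]
        assert best_matched_rank(paths, curated) == 2

    def test_no_match_none(self):
        paths = [ScoredPath(KGPath(("d", "g", "z"), ("p", "q")), 0.0, 1, 1)]
        assert best_matched_rank(paths, [["x", "y"]]) is None


class TestRankingMetrics:
    def test_mrr_hand_value(self):
        r = ranking_metrics([1, 2, 4], [10, 10, 10])
        assert r.mrr == pytest.approx((1 + 0.5 + 0.25) / 3)

    def test_hit_at_k_hand_value(self):
        r = ranking_metrics([1, 5, 12], [20, 20, 20], k_list=(10,))
        assert r.hit_at_k[10] == pytest.approx(2 / 3)

    def test_best_rank_percentile_100(self):
        r = ranking_metrics([1], [100])
        assert r.mpr == pytest.approx(100.0)

    def test_bounds_and_monotone_hits(self):
        rng = np.random.default_rng(3)
        n = 50
        ranks = [int(rng.integers(1, 21)) for _ in range(n)]
        r = ranking_metrics(ranks, [20] * n, k_list=(1, 3, 5, 10, 20))
        assert 0 < r.mrr <= 1
        assert 0 < r.mpr <= 100
        hits = [r.hit_at_k[k] for k in (1, 3, 5, 10, 20)]
        assert hits == sorted(hits)
        assert hits[-1] == 1.0

    def test_brute_force_recomputation(self):
        # independent recomputation from a raw score table
        rng = np.random.default_rng(1)
        scores = rng.normal(size=15)
        true_idx = 4
        rank = 1 + int(np.sum(scores > scores[true_idx]))
        r = ranking_metrics([rank], [15])
        assert r.mrr == pytest.approx(1.0 / rank)
        assert r.mpr == pytest.approx(100.0 * (15 - rank + 1) / 15)

    def test_errors(self):
        with pytest.raises(ValueError):
            ranking_metrics([], [])
        with pytest.raises(ValueError):
            ranking_metrics([5], [3])


class TestClassificationMetrics:
    classes = ("not_treat", "treat", "unknown")

    def test_perfect(self):
        y = ["treat", "not_treat", "unknown"] * 4
        r = classification_metrics(y, y, self.classes)
        assert r.acc == 1.0
        assert r.macro_f1 == 1.0

    def test_all_wrong(self):
        y_true = ["treat"] * 6
        y_pred = ["not_treat"] * 6
        r = classification_metrics(y_true, y_pred, self.classes)
        assert r.acc == 0.0

    def test_f1_hand_value(self):
        # treat: TP=8, FP=2, FN=2 -> F1 = 0.8
        y_true = (["treat"] * 8 + ["not_treat"] * 2 + ["treat"] * 2
                  + ["not_treat"] * 8 + ["unknown"] * 10)
        y_pred = (["treat"] * 8 + ["treat"] * 2 + ["not_treat"] * 2
                  + ["not_treat"] * 8 + ["unknown"] * 10)
        from sklearn.metrics import f1_score

        f1_treat = f1_score(y_true, y_pred, labels=["treat"], average="macro")
        assert f1_treat == pytest.approx(0.8)
        r = classification_metrics(y_true, y_pred, self.classes)
        # macro mean over the three classes, treat contributing 0.8
        assert r.macro_f1 == pytest.approx((0.8 + 0.8 + 1.0) / 3)

    def test_exclude_unknown(self):
        y_true = ["treat", "not_treat", "unknown", "unknown"]
        y_pred = ["treat", "not_treat", "treat", "unknown"]
        full = classification_metrics(y_true, y_pred, self.classes)
        two = classification_metrics(y_true, y_pred, self.classes,
                                     exclude_unknown=True)
        assert two.acc == 1.0
        assert two.macro_f1 == 1.0
        assert full.acc == pytest.approx(0.75)

    def test_absent_class_warns(self):
        with pytest.warns(UserWarning, match="unknown"):
            classification_metrics(["treat"], ["treat"], self.classes)
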