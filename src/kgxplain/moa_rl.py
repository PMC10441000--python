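"""Mechanism-of-action path finding as adversarial actor-critic RL on the KG.

The agent starts at a drug node and walks exactly ``T`` steps (a self-loop
action allows it to stay put).  Four subnetworks share the three-layer
MLP architecture but own separate parameters and embedding matrices:

* actor      -- masked softmax policy over the pruned action space,
* critic     -- state-action value via a dot product with the action embedding,
* path discriminator      -- demo-vs-actor classifier on (state, action),
* meta-path discriminator -- demo-vs-actor classifier on category sequences.

Rewards combine the discriminators' log-odds with a discounted terminal
reward from the drug-repurposing classifier.  Training is multistage:
behavior cloning, a discriminator-only warmup of ``z`` epochs with the
actor/critic frozen, then joint optimization of the TD-squared critic loss
and the TD-weighted REINFORCE actor loss with entropy regularization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, concat, masked_softmax
from .demo_paths import KGPath
from .drp import DRPModel, pair_features, predict_treat_proba
from .kg_store import KnowledgeGraph
from .nn import MLP3, Adam, Embedding, params_fingerprint
from .node_embeddings import EmbeddingTable
from .pair_data import LabeledPair, TREAT, UNKNOWN

logger = logging.getLogger(__name__)

SELF_LOOP = "SELF_LOOP"
DUMMY = "__DUMMY__"  # reserved embedding index 0
PROB_EPS = 1e-7


class MOATrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class MOAConfig:
    """Reward shaping, MDP shape, and training hyperparameters."""

    alpha_p: float = 0.1
    alpha_m: float = 0.1
    gamma: float = 0.99
    entropy_weight: float = 0.01
    T: int = 3
    K: int = 2
    z: int = 5
    neighbor_cap: int = 3000
    seed: int = 0
    # training knobs (defaults desk-scale)
    emb_dim: int = 32
    hidden_dim: int = 64
    lr: float = 1e-3
    epochs: int = 20
    episodes_per_epoch: int = 64
    bc_epochs: int = 20
    bc_lr: float = 1e-2

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_p <= 1.0):
            raise ValueError("alpha_p must be in [0, 1]")
        if not (0.0 <= self.alpha_m <= 1.0 - self.alpha_p + 1e-12):
            raise ValueError("alpha_m must be in [0, 1 - alpha_p]")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.entropy_weight < 0:
            raise ValueError("entropy_weight must be >= 0")


RewardConfig = MOAConfig


@dataclass(frozen=True)
class Action:
    predicate: str
    next: str


@dataclass(frozen=True)
class EnvState:
    drug: str
    current: str
    history: tuple[tuple[str, str], ...]  # most recent first, length K
    t: int

    def key(self) -> tuple:
        return (self.drug, self.current, self.history, self.t)


@dataclass
class Trajectory:
    states: list[EnvState]
    actions: list[Action]
    action_space_sizes: list[int]
    rewards: list[float] = field(default_factory=list)
    terminal_reward: float = 0.0

    @property
    def nodes(self) -> list[str]:
        return [self.states[0].drug] + [a.next for a in self.actions]


def td_loss(r: float, q_next: float, q: float) -> float:
    """Squared temporal-difference error ((R + Q(s', a')) - Q(s, a))^2."""
    return ((r + q_next) - q) ** 2


def combined_reward(cfg: MOAConfig, r_p: float, r_m: float, r_et: float,
                    t: int, T: int | None = None) -> float:
    """R_t = alpha_p R_p + alpha_m R_m + (1 - alpha_p - alpha_m) gamma^(T-t) R_e,T."""
    T = cfg.T if T is None else T
    return (
        cfg.alpha_p * r_p
        + cfg.alpha_m * r_m
        + (1.0 - cfg.alpha_p - cfg.alpha_m) * cfg.gamma ** (T - t) * r_et
    )


def terminal_reward(
    drp_model: DRPModel,
    emb: EmbeddingTable,
    drug: str,
    v_t: str,
    known_diseases_of_drug: set[str],
    disease_ids: set[str],
) -> float:
    """Four-branch terminal reward from the repurposing classifier."""
    if v_t in known_diseases_of_drug:
        return 1.0
    if v_t not in disease_ids:
        return -1.0
    proba, p_treat = predict_treat_proba(
        drp_model, pair_features(emb, [LabeledPair(drug, v_t, UNKNOWN)])
    )
    predicted = drp_model.classes[int(proba[0].argmax())]
    return float(p_treat[0]) if predicted == TREAT else 0.0


class MOAContext:
    """Indexes the graph for the MDP: action spaces, state vectors, batching."""

    def __init__(
        self,
        g: KnowledgeGraph,
        attr: EmbeddingTable,
        cfg: MOAConfig,
        pagerank: dict[str, float] | None = None,
    ):
        from .kg_store import pagerank_scores

        self.g = g
        self.cfg = cfg
        self.attr = attr
        self.pagerank = pagerank if pagerank is not None else pagerank_scores(g)

        self.node_ids = g.node_ids()
        self.node_index = {v: i + 1 for i, v in enumerate(self.node_ids)}  # 0 = dummy
        self.predicates = sorted(set(g.predicates()) | {SELF_LOOP})
        self.pred_index = {p: i + 1 for i, p in enumerate(self.predicates)}
        self.categories = sorted({n.category for n in g.nodes.values()})
        self.cat_index = {c: i + 1 for i, c in enumerate(self.categories)}

        d = attr.dim
        self.attr_matrix = np.zeros((len(self.node_ids) + 1, d))
        for v, i in self.node_index.items():
            self.attr_matrix[i] = attr[v]
        self.n_pred_onehot = len(self.predicates) + 1
        # state = drug + current + K history nodes (attr) + K history predicates (one-hot)
        self.state_dim = (2 + cfg.K) * d + cfg.K * self.n_pred_onehot
        self._action_cache: dict[str, list[Action]] = {}

    # -- MDP -------------------------------------------------------------

    def initial_state(self, drug: str) -> EnvState:
        return EnvState(
            drug=drug,
            current=drug,
            history=tuple((DUMMY, DUMMY) for _ in range(self.cfg.K)),
            t=0,
        )

    def action_space(self, state: EnvState) -> list[Action]:
        """Self-loop first, then sorted out-edges, PageRank-pruned to the cap."""
        cur = state.current
        cached = self._action_cache.get(cur)
        if cached is None:
            out = self.g.out_edges(cur)
            if len(out) > self.cfg.neighbor_cap:
                ranked = sorted(
                    out, key=lambda pn: (-self.pagerank[pn[1]], pn[1], pn[0])
                )
                out = sorted(ranked[: self.cfg.neighbor_cap])
            cached = [Action(SELF_LOOP, cur)] + [Action(p, n) for p, n in out]
            self._action_cache[cur] = cached
        return cached

    def env_step(self, state: EnvState, action: Action) -> EnvState:
        if state.t >= self.cfg.T:
            raise ValueError(f"episode over at t={state.t} (T={self.cfg.T})")
        if action not in self.action_space(state):
            raise ValueError(f"illegal action {action} at node {state.current!r}")
        history = ((state.current, action.predicate),) + state.history[:-1]
        return EnvState(
            drug=state.drug, current=action.next, history=history, t=state.t + 1
        )

    # -- vectorization ---------------------------------------------------

    def _attr_row(self, node: str) -> np.ndarray:
        return self.attr_matrix[self.node_index.get(node, 0)]

    def state_vector(self, state: EnvState) -> np.ndarray:
        parts = [self._attr_row(state.drug), self._attr_row(state.current)]
        for node, _ in state.history:
            parts.append(self._attr_row(node))
        for _, pred in state.history:
            onehot = np.zeros(self.n_pred_onehot)
            onehot[self.pred_index.get(pred, 0)] = 1.0
            parts.append(onehot)
        return np.concatenate(parts)

    def action_indices(self, actions: list[Action]) -> tuple[np.ndarray, np.ndarray]:
        preds = np.array([self.pred_index.get(a.predicate, 0) for a in actions])
        nodes = np.array([self.node_index.get(a.next, 0) for a in actions])
        return preds, nodes

    def metapath_indices(self, nodes: list[str]) -> np.ndarray:
        """Category-index sequence, padded to T+1 by repeating the last."""
        cats = [self.cat_index.get(self.g.category_of(v), 0) for v in nodes]
        while len(cats) < self.cfg.T + 1:
            cats.append(cats[-1])
        return np.array(cats[: self.cfg.T + 1])

    def batch_states(self, states: list[EnvState]) -> np.ndarray:
        return np.stack([self.state_vector(s) for s in states])

    def batch_action_spaces(
        self, spaces: list[list[Action]]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a_max = max(len(s) for s in spaces)
        b = len(spaces)
        preds = np.zeros((b, a_max), dtype=np.int64)
        nodes = np.zeros((b, a_max), dtype=np.int64)
        mask = np.zeros((b, a_max), dtype=bool)
        for i, space in enumerate(spaces):
            p, n = self.action_indices(space)
            preds[i, : len(space)] = p
            nodes[i, : len(space)] = n
            mask[i, : len(space)] = True
        return preds, nodes, mask


class _Subnetwork:
    """MLP + private node/predicate embedding matrices."""

    def __init__(self, ctx: MOAContext, in_dim: int, out_dim: int,
                 rng: np.random.Generator):
        cfg = ctx.cfg
        self.mlp = MLP3(in_dim, cfg.hidden_dim, out_dim, rng)
        self.node_emb = Embedding(len(ctx.node_ids) + 1, cfg.emb_dim, rng)
        self.pred_emb = Embedding(len(ctx.predicates) + 1, cfg.emb_dim, rng)

    def action_embedding(self, preds: np.ndarray, nodes: np.ndarray) -> Tensor:
        return concat([self.pred_emb(preds), self.node_emb(nodes)], axis=-1)

    def parameters(self) -> list[Tensor]:
        return (self.mlp.parameters() + self.node_emb.parameters()
                + self.pred_emb.parameters())

    def train(self, mode: bool = True) -> None:
        self.mlp.train(mode)

    def state_arrays(self) -> list[np.ndarray]:
        return self.mlp.state_arrays() + [self.node_emb.table.data,
                                          self.pred_emb.table.data]


class MOAAgent:
    """The four subnetworks plus forward helpers."""

    def __init__(self, ctx: MOAContext, seed: int | None = None):
        self.ctx = ctx
        cfg = ctx.cfg
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        two_d = 2 * cfg.emb_dim
        self.actor = _Subnetwork(ctx, ctx.state_dim, two_d, rng)
        self.critic = _Subnetwork(ctx, ctx.state_dim, two_d, rng)
        self.path_disc = _Subnetwork(ctx, ctx.state_dim + two_d, 1, rng)
        self.meta_mlp = MLP3(cfg.emb_dim * (cfg.T + 1), cfg.hidden_dim, 1, rng)
        self.cat_emb = Embedding(len(ctx.categories) + 1, cfg.emb_dim, rng)

    # -- forward passes --------------------------------------------------

    def policy_batch(self, s: np.ndarray, preds: np.ndarray, nodes: np.ndarray,
                     mask: np.ndarray) -> Tensor:
        """Masked softmax policy over padded action spaces."""
        out = self.actor.mlp(Tensor(s))                      # (B, 2d)
        aemb = self.actor.action_embedding(preds, nodes)     # (B, A, 2d)
        b = s.shape[0]
        logits = (aemb * out.reshape(b, 1, -1)).sum(axis=2)  # (B, A)
        return masked_softmax(logits, mask)

    def action_probs(self, state: EnvState, actions: list[Action]) -> np.ndarray:
        """Eval-mode policy distribution for a single state."""
        self.actor.train(False)
        s = self.ctx.batch_states([state])
        preds, nodes, mask = self.ctx.batch_action_spaces([actions])
        return self.policy_batch(s, preds, nodes, mask).data[0]

    def q_batch(self, s: np.ndarray, preds: np.ndarray, nodes: np.ndarray) -> Tensor:
        out = self.critic.mlp(Tensor(s))
        aemb = self.critic.action_embedding(preds, nodes)
        return (out * aemb).sum(axis=1)

    def q_value(self, state: EnvState, action: Action) -> float:
        self.critic.train(False)
        preds, nodes = self.ctx.action_indices([action])
        return float(self.q_batch(self.ctx.batch_states([state]), preds, nodes).data[0])

    def path_disc_prob(self, s: np.ndarray, preds: np.ndarray,
                       nodes: np.ndarray) -> Tensor:
        aemb = self.path_disc.action_embedding(preds, nodes)
        x = concat([Tensor(s), aemb], axis=1)
        return self.path_disc.mlp(x).reshape(-1).sigmoid()

    def meta_disc_prob(self, cat_idx: np.ndarray) -> Tensor:
        b = cat_idx.shape[0]
        emb = self.cat_emb(cat_idx).reshape(b, -1)
        return self.meta_mlp(emb).reshape(-1).sigmoid()

    def discriminator_rewards(self, state: EnvState, action: Action,
                              metapath_nodes: list[str]) -> tuple[float, float]:
        """(R_p, R_m) log-odds rewards, probabilities clipped to [eps, 1-eps]."""
        self.path_disc.train(False)
        self.meta_mlp.train(False)
        s = self.ctx.batch_states([state])
        preds, nodes = self.ctx.action_indices([action])
        d_p = float(self.path_disc_prob(s, preds, nodes).data[0])
        cats = self.ctx.metapath_indices(metapath_nodes)[None, :]
        d_m = float(self.meta_disc_prob(cats).data[0])
        return log_odds(d_p), log_odds(d_m)

    # -- bookkeeping -----------------------------------------------------

    def actor_critic_arrays(self) -> list[np.ndarray]:
        return self.actor.state_arrays() + self.critic.state_arrays()

    def fingerprint_actor_critic(self) -> bytes:
        return params_fingerprint(self.actor_critic_arrays())


def log_odds(p: float, eps: float = PROB_EPS) -> float:
    p = min(max(p, eps), 1.0 - eps)
    return math.log(p) - math.log(1.0 - p)


def actor_policy(agent: MOAAgent, state: EnvState,
                 actions: list[Action]) -> np.ndarray:
    return agent.action_probs(state, actions)


def critic_value(agent: MOAAgent, state: EnvState, action: Action) -> float:
    return agent.q_value(state, action)


# -- demonstration segments ---------------------------------------------


@dataclass
class Segment:
    state: EnvState
    action: Action
    path_nodes: list[str]  # nodes visited up to and including the action target

    def key(self) -> tuple:
        return (self.state.key(), self.action.predicate, self.action.next)


def path_segments(ctx: MOAContext, path: KGPath) -> list[Segment]:
    """Walk a demonstration path through the environment, yielding segments."""
    state = ctx.initial_state(path.nodes[0])
    segments = []
    visited = [path.nodes[0]]
    for pred, nxt in zip(path.predicates, path.nodes[1:]):
        action = Action(pred, nxt)
        visited = visited + [nxt]
        segments.append(Segment(state, action, list(visited)))
        state = ctx.env_step(state, action)
    return segments


def discriminator_losses(
    agent: MOAAgent,
    demo_segments: list[Segment],
    actor_segments: list[Segment],
    demo_metapaths: list[list[str]],
    actor_metapaths: list[list[str]],
) -> tuple[Tensor, Tensor]:
    """Binary cross-entropy losses for both discriminators.

    Actor segments identical to a demonstration segment are excluded from
    the negatives by the caller; this function requires both classes
    non-empty.
    """
    if not demo_segments or not actor_segments:
        raise ValueError("path discriminator needs both positive and negative segments")
    if not demo_metapaths or not actor_metapaths:
        raise ValueError("meta-path discriminator needs both classes")
    ctx = agent.ctx

    def seg_batch(segments):
        s = ctx.batch_states([seg.state for seg in segments])
        preds, nodes = ctx.action_indices([seg.action for seg in segments])
        return s, preds, nodes

    d_pos = agent.path_disc_prob(*seg_batch(demo_segments)).clip_probability()
    d_neg = agent.path_disc_prob(*seg_batch(actor_segments)).clip_probability()
    l_p = -(d_pos.log().mean()) - ((1.0 - d_neg).log().mean())

    m_pos = np.stack([ctx.metapath_indices(m) for m in demo_metapaths])
    m_neg = np.stack([ctx.metapath_indices(m) for m in actor_metapaths])
    dm_pos = agent.meta_disc_prob(m_pos).clip_probability()
    dm_neg = agent.meta_disc_prob(m_neg).clip_probability()
    l_m = -(dm_pos.log().mean()) - ((1.0 - dm_neg).log().mean())
    return l_p, l_m


def behavior_clone(
    agent: MOAAgent,
    demo_paths: list[KGPath],
    epochs: int | None = None,
    lr: float | None = None,
    loss_log: list[float] | None = None,
) -> None:
    """Warm-start the actor: MSE between the policy distribution and the
    one-hot demonstration action at every demonstration state."""
    cfg = agent.ctx.cfg
    epochs = cfg.bc_epochs if epochs is None else epochs
    lr = cfg.bc_lr if lr is None else lr
    if epochs == 0:
        return
    ctx = agent.ctx
    samples = []
    for path in demo_paths:
        for seg in path_segments(ctx, path):
            space = ctx.action_space(seg.state)
            try:
                target = space.index(seg.action)
            except ValueError:  # pruned out of the action space
                continue
            samples.append((seg.state, space, target))
    if not samples:
        return
    s = ctx.batch_states([x[0] for x in samples])
    preds, nodes, mask = ctx.batch_action_spaces([x[1] for x in samples])
    onehot = np.zeros(mask.shape)
    for i, (_, _, tgt) in enumerate(samples):
        onehot[i, tgt] = 1.0
    opt = Adam(agent.actor.parameters(), lr=lr)
    agent.actor.train(True)
    for epoch in range(epochs):
        probs = agent.policy_batch(s, preds, nodes, mask)
        loss = (((probs - onehot) ** 2) * mask).sum(axis=1).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        if loss_log is not None:
            loss_log.append(float(loss.data))
    agent.actor.train(False)


# -- full training -------------------------------------------------------


@dataclass
class TrainLogRow:
    epoch: int
    stage: str
    l_a: float
    l_c: float
    l_p: float
    l_m: float
    mean_reward: float


def _rollout(
    agent: MOAAgent, drugs: list[str], rng: np.random.Generator
) -> list[Trajectory]:
    ctx = agent.ctx
    agent.actor.train(False)
    trajectories = []
    states = [ctx.initial_state(d) for d in drugs]
    trajs = [Trajectory(states=[s], actions=[], action_space_sizes=[]) for s in states]
    for _ in range(ctx.cfg.T):
        spaces = [ctx.action_space(t.states[-1]) for t in trajs]
        s = ctx.batch_states([t.states[-1] for t in trajs])
        preds, nodes, mask = ctx.batch_action_spaces(spaces)
        probs = agent.policy_batch(s, preds, nodes, mask).data
        for i, traj in enumerate(trajs):
            p = probs[i, : len(spaces[i])]
            p = p / p.sum()
            choice = rng.choice(len(spaces[i]), p=p)
            action = spaces[i][choice]
            traj.actions.append(action)
            traj.action_space_sizes.append(len(spaces[i]))
            traj.states.append(ctx.env_step(traj.states[-1], action))
    return trajs


def train_moa(
    ctx: MOAContext,
    drp_model: DRPModel,
    emb: EmbeddingTable,
    demo_paths: list[KGPath],
    train_positives: list[LabeledPair],
    agent: MOAAgent | None = None,
    log: list[TrainLogRow] | None = None,
) -> MOAAgent:
    """Multistage training: behavior cloning, discriminator warmup, joint.

    With ``alpha_p == alpha_m == 0`` and no demonstration paths this reduces
    to plain actor-critic with terminal-only reward shaping.
    """
    cfg = ctx.cfg
    rng = np.random.default_rng(cfg.seed)
    if agent is None:
        agent = MOAAgent(ctx)
    use_demos = bool(demo_paths) and (cfg.alpha_p > 0 or cfg.alpha_m > 0)

    known_by_drug: dict[str, set[str]] = {}
    for p in train_positives:
        known_by_drug.setdefault(p.drug, set()).add(p.disease)
    disease_ids = ctx.g.disease_ids()
    start_drugs = sorted({p.drug for p in train_positives})
    if not start_drugs:
        raise MOATrainingError("no training drugs to start episodes from")

    demo_segments: list[Segment] = []
    demo_keys: set[tuple] = set()
    demo_mps: list[list[str]] = []
    demo_mp_keys: set[tuple] = set()
    if use_demos:
        behavior_clone(agent, demo_paths)
        for path in demo_paths:
            for seg in path_segments(ctx, path):
                demo_segments.append(seg)
                demo_keys.add(seg.key())
            mp = list(path.nodes)
            demo_mps.append(mp)
            demo_mp_keys.add(tuple(ctx.metapath_indices(mp)))

    opt_ac = Adam(agent.actor.parameters() + agent.critic.parameters(), lr=cfg.lr)
    opt_disc = Adam(
        agent.path_disc.parameters() + agent.meta_mlp.parameters()
        + agent.cat_emb.parameters(),
        lr=cfg.lr,
    )

    warmup = cfg.z if use_demos else 0
    for epoch in range(cfg.epochs):
        stage = "warmup" if epoch < warmup else "joint"
        starts = [start_drugs[rng.integers(len(start_drugs))]
                  for _ in range(cfg.episodes_per_epoch)]
        trajs = _rollout(agent, starts, rng)

        # terminal rewards
        for traj in trajs:
            drug = traj.states[0].drug
            v_t = traj.states[-1].current
            traj.terminal_reward = terminal_reward(
                drp_model, emb, drug, v_t, known_by_drug.get(drug, set()),
                disease_ids,
            )

        # discriminator update on this rollout batch
        l_p_val = l_m_val = 0.0
        if use_demos:
            neg_segments, neg_mps = [], []
            for traj in trajs:
                nodes_so_far = [traj.states[0].drug]
                for state, action in zip(traj.states[:-1], traj.actions):
                    nodes_so_far = nodes_so_far + [action.next]
                    seg = Segment(state, action, list(nodes_so_far))
                    if seg.key() not in demo_keys:
                        neg_segments.append(seg)
                mp = traj.nodes
                if tuple(ctx.metapath_indices(mp)) not in demo_mp_keys:
                    neg_mps.append(mp)
            if neg_segments and neg_mps:
                agent.path_disc.train(True)
                agent.meta_mlp.train(True)
                l_p, l_m = discriminator_losses(
                    agent, demo_segments, neg_segments, demo_mps, neg_mps
                )
                opt_disc.zero_grad()
                (l_p + l_m).backward()
                opt_disc.step()
                l_p_val, l_m_val = float(l_p.data), float(l_m.data)
                agent.path_disc.train(False)
                agent.meta_mlp.train(False)

        # shaped per-step rewards (discriminators held fixed)
        for traj in trajs:
            traj.rewards = []
            nodes_so_far = [traj.states[0].drug]
            for i, (state, action) in enumerate(zip(traj.states[:-1], traj.actions)):
                nodes_so_far = nodes_so_far + [action.next]
                if use_demos:
                    r_p, r_m = agent.discriminator_rewards(
                        state, action, list(nodes_so_far)
                    )
                else:
                    r_p = r_m = 0.0
                traj.rewards.append(
                    combined_reward(cfg, r_p, r_m, traj.terminal_reward, i + 1)
                )

        l_a_val = l_c_val = 0.0
        mean_reward = float(np.mean([t.terminal_reward for t in trajs]))
        if stage == "joint":
            l_a_val, l_c_val = _joint_update(agent, trajs, opt_ac)
            if not (math.isfinite(l_a_val) and math.isfinite(l_c_val)):
                raise MOATrainingError(
                    f"non-finite joint loss at epoch {epoch}: "
                    f"L_a={l_a_val}, L_c={l_c_val}"
                )
        if log is not None:
            log.append(TrainLogRow(epoch, stage, l_a_val, l_c_val,
                                   l_p_val, l_m_val, mean_reward))
        logger.info(
            "epoch %d [%s] L_a=%.4f L_c=%.4f L_p=%.4f L_m=%.4f reward=%.4f",
            epoch, stage, l_a_val, l_c_val, l_p_val, l_m_val, mean_reward,
        )
    return agent


def _joint_update(agent: MOAAgent, trajs: list[Trajectory],
                  opt: Adam) -> tuple[float, float]:
    """One joint actor-critic step over all (state, action) pairs in the batch."""
    ctx = agent.ctx
    cfg = ctx.cfg
    flat_states, flat_spaces, flat_choice, flat_rewards = [], [], [], []
    next_states, next_actions, is_last = [], [], []
    for traj in trajs:
        for i, (state, action) in enumerate(zip(traj.states[:-1], traj.actions)):
            flat_states.append(state)
            space = ctx.action_space(state)
            flat_spaces.append(space)
            flat_choice.append(space.index(action))
            flat_rewards.append(traj.rewards[i])
            last = i == len(traj.actions) - 1
            is_last.append(last)
            next_states.append(traj.states[i + 1])
            next_actions.append(traj.actions[i + 1] if not last else action)

    s = ctx.batch_states(flat_states)
    preds, nodes, mask = ctx.batch_action_spaces(flat_spaces)
    taken_preds = preds[np.arange(len(flat_choice)), flat_choice]
    taken_nodes = nodes[np.arange(len(flat_choice)), flat_choice]

    agent.actor.train(True)
    agent.critic.train(True)
    q = agent.q_batch(s, taken_preds, taken_nodes)
    s_next = ctx.batch_states(next_states)
    np_preds, np_nodes = ctx.action_indices(next_actions)
    q_next = agent.q_batch(s_next, np_preds, np_nodes)
    bootstrap = np.where(is_last, 0.0, 1.0)
    target = Tensor(np.asarray(flat_rewards)) + q_next.detach() * bootstrap
    td = target - q
    l_c = (td ** 2).mean()

    probs = agent.policy_batch(s, preds, nodes, mask)
    onehot = np.zeros(mask.shape)
    onehot[np.arange(len(flat_choice)), flat_choice] = 1.0
    log_probs = probs.clip_probability().log()
    chosen_logp = (log_probs * onehot).sum(axis=1)
    entropy = -((probs * log_probs) * mask).sum(axis=1)
    l_a = -(Tensor(td.data) * chosen_logp).mean() - cfg.entropy_weight * entropy.mean()

    loss = l_a + l_c
    opt.zero_grad()
    loss.backward()
    opt.step()
    agent.actor.train(False)
    agent.critic.train(False)
    return float(l_a.data), float(l_c.data)
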