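"""Node embeddings: attribute features from a pluggable text encoder (with PCA
compression) and neighborhood-aware graph embeddings trained with the
random-walk skip-gram negative-sampling objective.

The graph encoder is a two-layer mean-aggregating network: each layer
concatenates a node's current feature with the mean feature of its (in+out)
neighbors and applies a linear map + ELU (last layer linear).  It is trained
so that nodes co-occurring on directed random walks have similar output
embeddings while ``k`` negatives drawn from the degree^0.75 unigram
distribution are pushed apart:

    loss(u, v) = -log sigma(z_u . z_v) - sum_{n=1..k} log sigma(-z_u . z_vn)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .autograd import Tensor, concat, spmm
from .kg_store import KnowledgeGraph
from .nn import Adam

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingTable:
    dim: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for v, vec in self.vectors.items():
            if len(vec) != self.dim:
                raise ValueError(
                    f"vector for {v!r} has length {len(vec)}, expected {self.dim}"
                )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite embedding entries for {v!r}")

    def matrix(self, order: list[str]) -> np.ndarray:
        return np.stack([self.vectors[v] for v in order])

    def __getitem__(self, v: str) -> np.ndarray:
        return self.vectors[v]

    def __contains__(self, v: str) -> bool:
        return v in self.vectors


@dataclass(frozen=True)
class GraphEmbedConfig:
    walk_length: int = 8
    walks_per_node: int = 10
    window: int = 5
    num_negatives: int = 20
    layers: int = 2
    hidden_dim: int = 64
    epochs: int = 5
    batch_size: int = 1024
    lr: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("walk_length", "walks_per_node", "window", "num_negatives",
                     "layers", "hidden_dim", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class HashingTextEncoder:
    """Deterministic seeded feature-hashing text encoder.

    A desk-scale stand-in for a biomedical language model: each token hashes
    into ``dim`` buckets with a +-1 sign, and the bucket counts are
    L2-normalized.  Deterministic given (dim, seed).
    """

    def __init__(self, dim: int = 256, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in text.lower().split():
            h = hashlib.blake2b(
                token.encode(), digest_size=8, salt=str(self.seed).encode()[:16]
            ).digest()
            val = int.from_bytes(h, "little")
            vec[val % self.dim] += 1.0 if (val >> 32) % 2 == 0 else -1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def attribute_embeddings(g: KnowledgeGraph, encoder=None) -> EmbeddingTable:
    """Embed every node from the string ``name + " " + category``."""
    if encoder is None:
        encoder = HashingTextEncoder()
    vectors: dict[str, np.ndarray] = {}
    dim = None
    for v in g.node_ids():
        node = g.nodes[v]
        vec = np.asarray(encoder(f"{node.name} {node.category}"), dtype=np.float64)
        if dim is None:
            dim = len(vec)
        elif len(vec) != dim:
            raise ValueError(
                f"encoder dimension mismatch at node {v!r}: {len(vec)} != {dim}"
            )
        vectors[v] = vec
    return EmbeddingTable(dim=dim, vectors=vectors)


def reduce_pca(t: EmbeddingTable, target_dim: int = 100, seed: int = 0) -> EmbeddingTable:
    """Project onto the top principal components; pass through if already small."""
    if len(t.vectors) < 2:
        raise ValueError("PCA needs at least 2 nodes")
    if t.dim <= target_dim:
        return t
    order = sorted(t.vectors)
    x = t.matrix(order)
    n_comp = min(target_dim, len(order))
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    z = pca.fit_transform(x)
    return EmbeddingTable(dim=n_comp, vectors={v: z[i] for i, v in enumerate(order)})


def walk_corpus(g: KnowledgeGraph, cfg: GraphEmbedConfig) -> list[tuple[str, str]]:
    """(center, context) pairs from directed uniform random walks.

    ``walks_per_node`` walks of length ``walk_length`` start from every node;
    dead ends terminate the walk early.  Within each walk, every ordered pair
    of distinct nodes at distance <= window is emitted.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs: list[tuple[str, str]] = []
    for start in g.node_ids():
        for _ in range(cfg.walks_per_node):
            walk = [start]
            cur = start
            for _ in range(cfg.walk_length):
                nbrs = g.out_edges(cur)
                if not nbrs:
                    break
                cur = nbrs[rng.integers(len(nbrs))][1]
                walk.append(cur)
            for i, u in enumerate(walk):
                for j in range(max(0, i - cfg.window), min(len(walk), i + cfg.window + 1)):
                    if i != j and walk[j] != u:
                        pairs.append((u, walk[j]))
    return pairs


class _MeanAggregator:
    """Stack of mean-aggregation layers shared by training and inference."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, layers: int,
                 rng: np.random.Generator):
        dims = [in_dim] + [hidden_dim] * (layers - 1) + [out_dim]
        self.weights = []
        for i in range(layers):
            scale = np.sqrt(6.0 / (2 * dims[i] + dims[i + 1]))
            self.weights.append(
                Tensor.param(rng.uniform(-scale, scale, size=(2 * dims[i], dims[i + 1])))
            )

    def __call__(self, x: Tensor, adj: sp.spmatrix) -> Tensor:
        h = x
        for i, w in enumerate(self.weights):
            agg = spmm(adj, h)
            h = concat([h, agg], axis=1) @ w
            if i < len(self.weights) - 1:
                h = h.elu()
        return h

    def parameters(self) -> list[Tensor]:
        return list(self.weights)


def _mean_adjacency(g: KnowledgeGraph, order: list[str]) -> sp.csr_matrix:
    idx = {v: i for i, v in enumerate(order)}
    rows, cols, vals = [], [], []
    for v in order:
        nbrs = g.neighbors(v)
        if not nbrs:
            nbrs = [v]  # isolated node aggregates itself
        w = 1.0 / len(nbrs)
        for u in nbrs:
            rows.append(idx[v])
            cols.append(idx[u])
            vals.append(w)
    n = len(order)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


class EmbeddingTrainingError(RuntimeError):
    pass


def negative_sampling_loss(zu: Tensor, zv: Tensor, zn: Tensor) -> Tensor:
    """Mean per-pair loss -log s(zu.zv) - sum_n log s(-zu.zn).

    ``zu``/``zv`` are (b, d); ``zn`` is (b, k, d).  With all-orthogonal
    (zero-dot-product) vectors the per-pair value is (1 + k) log 2.
    """
    b, k, _ = zn.shape
    pos = (zu * zv).sum(axis=1)
    neg = (zu.reshape(b, 1, -1) * zn).sum(axis=2)
    return (-(pos.logsigmoid()) - (-neg).logsigmoid().sum(axis=1)).mean()


def train_graph_embeddings(
    g: KnowledgeGraph,
    attr: EmbeddingTable,
    cfg: GraphEmbedConfig,
    loss_log: list[float] | None = None,
) -> EmbeddingTable:
    """Train the mean-aggregating encoder on the walk corpus; return embeddings."""
    order = g.node_ids()
    for v in order:
        if v not in attr:
            raise ValueError(f"attribute embeddings missing node {v!r}")
    rng = np.random.default_rng(cfg.seed)
    x = Tensor(attr.matrix(order))
    adj = _mean_adjacency(g, order)
    model = _MeanAggregator(attr.dim, cfg.hidden_dim, cfg.hidden_dim,
                            cfg.layers, rng)
    opt = Adam(model.parameters(), lr=cfg.lr)

    idx = {v: i for i, v in enumerate(order)}
    corpus = walk_corpus(g, cfg)
    if not corpus:
        logger.warning("empty walk corpus; returning untrained encoder output")
        z = model(x, adj).data
        return EmbeddingTable(dim=z.shape[1], vectors={v: z[i] for i, v in enumerate(order)})
    centers = np.array([idx[u] for u, _ in corpus])
    contexts = np.array([idx[v] for _, v in corpus])

    # degree^0.75 unigram negative-sampling distribution
    deg = np.zeros(len(order))
    for e in g.edges:
        deg[idx[e.subject]] += 1
        deg[idx[e.object]] += 1
    p_neg = (deg + 1e-12) ** 0.75
    p_neg /= p_neg.sum()

    n_pairs = len(centers)
    k = cfg.num_negatives
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n_pairs)
        epoch_loss = 0.0
        for lo in range(0, n_pairs, cfg.batch_size):
            sel = perm[lo:lo + cfg.batch_size]
            b = len(sel)
            negs = rng.choice(len(order), size=(b, k), p=p_neg)
            z = model(x, adj)
            zu = z.take_rows(centers[sel])              # (b, d)
            zv = z.take_rows(contexts[sel])             # (b, d)
            zn = z.take_rows(negs.ravel()).reshape(b, k, -1)
            loss = negative_sampling_loss(zu, zv, zn)
            if not np.isfinite(loss.data):
                raise EmbeddingTrainingError(
                    f"non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * b
        epoch_loss /= n_pairs
        if loss_log is not None:
            loss_log.append(epoch_loss)
        logger.info("embedding epoch %d: loss %.4f", epoch, epoch_loss)

    z = model(x, adj).data
    return EmbeddingTable(dim=z.shape[1], vectors={v: z[i] for i, v in enumerate(order)})


# -- I/O -----------------------------------------------------------------

def save_embeddings(t: EmbeddingTable, path: str, meta: dict | None = None) -> None:
    order = sorted(t.vectors)
    df = pd.DataFrame(t.matrix(order))
    df.insert(0, "id", order)
    df.to_csv(path, sep="\t", index=False, header=False)
    if meta is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def load_embeddings(path: str) -> EmbeddingTable:
    df = pd.read_csv(path, sep="\t", header=None)
    ids = df.iloc[:, 0].astype(str).tolist()
    mat = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return EmbeddingTable(dim=mat.shape[1],
                          vectors={v: mat[i] for i, v in enumerate(ids)})
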