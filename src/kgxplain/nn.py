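"""Feed-forward building blocks on top of the local autograd: linear layers,
batch normalization, the shared three-layer MLP architecture, embeddings and
an Adam optimizer."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(6.0 / (in_dim + out_dim))  # Xavier uniform
        self.W = Tensor.param(rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.b = Tensor.param(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class BatchNorm1d:
    """Batch normalization with running statistics.

    Training mode normalizes by batch statistics (falling back to running
    statistics for singleton batches); eval mode always uses running stats.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor.param(np.ones(dim))
        self.beta = Tensor.param(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.data.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel()
            )
            norm = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            norm = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return norm * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class MLP3:
    """Three linear layers with batch-norm + ELU after the first two."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int, rng):
        self.l1 = Linear(in_dim, hidden_dim, rng)
        self.bn1 = BatchNorm1d(hidden_dim)
        self.l2 = Linear(hidden_dim, hidden_dim, rng)
        self.bn2 = BatchNorm1d(hidden_dim)
        self.l3 = Linear(hidden_dim, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.l1(x)).elu()
        h = self.bn2(self.l2(h)).elu()
        return self.l3(h)

    def train(self, mode: bool = True) -> None:
        self.bn1.training = mode
        self.bn2.training = mode

    def parameters(self) -> list[Tensor]:
        return self.l1.parameters() + self.bn1.parameters() + \
            self.l2.parameters() + self.bn2.parameters() + self.l3.parameters()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()] + [
            self.bn1.running_mean, self.bn1.running_var,
            self.bn2.running_mean, self.bn2.running_var,
        ]


class Embedding:
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.table = Tensor.param(rng.normal(0.0, 0.1, size=(n, dim)))

    def __call__(self, idx) -> Tensor:
        return self.table.take_rows(np.asarray(idx))

    def parameters(self) -> list[Tensor]:
        return [self.table]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


def params_fingerprint(params: list[np.ndarray]) -> bytes:
    """Byte-level fingerprint of a parameter list (for freeze checks)."""
    import hashlib

    h = hashlib.sha256()
    for a in params:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.digest()
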