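"""Batch/domain classifier: how separable are the batches?

A small feed-forward network (one relu hidden layer, softmax output over the
k batches) is trained to predict each observation's batch from its expression
profile. Its held-out accuracy (DomainAcc) measures batch separability: near
chance means the batches are statistically indistinguishable, near 1 means a
strong batch effect. The accept rate 1 - DomainAcc is the classifier's
contribution to the composite score.

Class imbalance across batches is handled by the focal loss
-alpha (1 - P_t)^gamma log(P_t), which down-weights easy examples; training
is plain mini-batch stochastic gradient descent, fully seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_P_FLOOR = 1e-12


@dataclass
class ClassifierConfig:
    hidden_units: int = 128
    alpha: float = 1.0
    gamma: float = 2.0
    learning_rate: float = 0.01
    epochs: int = 100
    train_fraction: float = 0.7
    batch_size: int = 64
    seed: int = 0
    features: str = "normalized"  # "normalized" gene matrix or "pca"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class ClassifierResult:
    n_batch: int
    n_sample: int
    train_size: int
    domain_acc: float
    accept_rate: float
    loss_history: list[float]

    def to_dict(self) -> dict:
        return {"n_batch": self.n_batch, "n_sample": self.n_sample,
                "train_size": self.train_size, "domain_acc": self.domain_acc,
                "accept_rate": self.accept_rate}


def focal_loss(prob_true_class, alpha: float = 1.0, gamma: float = 2.0) -> float:
    """Focal loss -alpha (1 - P_t)^gamma log(P_t), averaged when vectorized.

    At gamma=0, alpha=1 this reduces exactly to cross-entropy. P_t is clamped
    at 1e-12 from below so a confidently wrong prediction yields a large but
    finite loss.
    """
    p = np.clip(np.asarray(prob_true_class, dtype=float), _P_FLOOR, 1.0)
    return float(np.mean(-alpha * (1.0 - p) ** gamma * np.log(p)))


def stratified_split(n: int, batch: np.ndarray, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test split with exact global train size.

    The train set has exactly floor(train_fraction * N) members; per-batch
    allocations start at the per-batch floor and the remainder is assigned by
    largest fractional part (ties toward the alphabetically earlier batch),
    so stratification holds within rounding.
    """
    batch = np.asarray(batch).astype(str)
    if len(batch) != n:
        raise ValueError("batch labels must have length N")
    # guard against float error in train_fraction * n (e.g. 0.7 * 360)
    target = math.floor(train_fraction * n + 1e-9)
    if target == 0 or target == n:
        raise ValueError(f"train_fraction={train_fraction} yields an empty split for N={n}")
    names = sorted(set(batch))
    sizes = {b: int((batch == b).sum()) for b in names}
    if any(s < 2 for s in sizes.values()):
        raise ValueError("every batch needs at least two observations to split")
    quota = {b: train_fraction * sizes[b] for b in names}
    alloc = {b: math.floor(quota[b] + 1e-9) for b in names}
    remainder = target - sum(alloc.values())
    if remainder > 0:
        by_frac = sorted(names, key=lambda b: (-(quota[b] - alloc[b]), b))
        for b in by_frac[:remainder]:
            alloc[b] += 1
    elif remainder < 0:
        by_frac = sorted(names, key=lambda b: (quota[b] - alloc[b], b))
        for b in by_frac[:-remainder]:
            alloc[b] -= 1
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for b in names:
        idx = np.flatnonzero(batch == b)
        rng.shuffle(idx)
        train_parts.append(idx[:alloc[b]])
        test_parts.append(idx[alloc[b]:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    assert len(train) == target
    return train, test


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _FocalMLP:
    """One relu hidden layer + softmax output, trained by SGD on focal loss."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        s1 = math.sqrt(2.0 / n_in)
        s2 = math.sqrt(2.0 / n_hidden)
        self.w1 = rng.normal(0.0, s1, size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.w2 = rng.normal(0.0, s2, size=(n_hidden, n_out))
        self.b2 = np.zeros(n_out)

    def forward(self, x: np.ndarray):
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        return h, _softmax(h @ self.w2 + self.b2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        _, p = self.forward(x)
        return p.argmax(axis=1)

    def step(self, x: np.ndarray, y: np.ndarray, lr: float,
             alpha: float, gamma: float) -> float:
        """One SGD step on a mini-batch; returns the batch focal loss."""
        m = len(y)
        h, p = self.forward(x)
        pt = np.clip(p[np.arange(m), y], _P_FLOOR, 1.0)
        loss = float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))
        # dL/dp_t for the focal loss, then through softmax:
        # dL/dz_j = g * p_t (delta_tj - p_j) with g = dL/dp_t
        one_minus = 1.0 - pt
        with np.errstate(divide="ignore"):
            pow_gm1 = np.where(one_minus > 0.0, one_minus ** (gamma - 1.0), 0.0)
        g = -alpha * (one_minus ** gamma / pt - gamma * pow_gm1 * np.log(pt))
        dz = -p * (g * pt)[:, None]
        dz[np.arange(m), y] += g * pt
        dz /= m
        dw2 = h.T @ dz
        db2 = dz.sum(axis=0)
        dh = dz @ self.w2.T
        dh[h <= 0.0] = 0.0
        dw1 = x.T @ dh
        db1 = dh.sum(axis=0)
        self.w1 -= lr * dw1
        self.b1 -= lr * db1
        self.w2 -= lr * dw2
        self.b2 -= lr * db2
        return loss


def train_domain_classifier(dataset, config: ClassifierConfig | None = None,
                            features: np.ndarray | None = None) -> ClassifierResult:
    """Train the batch classifier and score it on the held-out split.

    Features default to the normalized gene matrix; pass ``features`` to
    evaluate a corrected embedding instead, or set ``config.features="pca"``.
    """
    config = config or ClassifierConfig()
    batch = np.asarray(dataset.batch).astype(str)
    names = sorted(set(batch))
    if len(names) < 2:
        raise ValueError("domain classifier needs at least two batches")
    y = np.searchsorted(names, batch)

    if features is None:
        if config.features == "pca":
            if "pca" not in dataset.embeddings:
                raise KeyError('pca features requested but embedding "pca" missing')
            features = dataset.embeddings["pca"]
        else:
            if "normalized" not in dataset.layers:
                from .preprocess import minmax_log_normalize

                dataset.layers["normalized"] = minmax_log_normalize(dataset.matrix)
            features = dataset.layers["normalized"]
    x = np.asarray(features, dtype=float)
    # standardize features so the fixed default learning rate behaves across spaces
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0.0] = 1.0
    x = (x - mu) / sd

    n = len(y)
    train_idx, test_idx = stratified_split(n, batch, config.train_fraction, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    model = _FocalMLP(x.shape[1], config.hidden_units, len(names), rng)

    loss_history: list[float] = []
    order = train_idx.copy()
    for _ in range(config.epochs):
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            loss = model.step(x[sel], y[sel], config.learning_rate,
                              config.alpha, config.gamma)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite focal loss at epoch {len(loss_history)}; "
                    f"lr={config.learning_rate}, hidden={config.hidden_units}"
                )
            losses.append(loss)
        loss_history.append(float(np.mean(losses)))

    acc = float(np.mean(model.predict(x[test_idx]) == y[test_idx]))
    return ClassifierResult(n_batch=len(names), n_sample=n,
                            train_size=len(train_idx), domain_acc=acc,
                            accept_rate=1.0 - acc, loss_history=loss_history)
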