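"""Ensemble MLP classifiers for per-residue scoring.

Each branch model is a 2-hidden-layer perceptron (ReLU, ReLU, sigmoid)
trained with Adam on binary cross-entropy over a class-balanced subsample.
Dropout acts on hidden activations only; by default the inverted variant
(mask scaled by 1/p_d during training) is used so eval-mode activations have
the same expectation. Five members with derived seeds are trained and their
eval-mode outputs averaged.

Implemented directly in NumPy: the networks are tiny (tens of units) and a
hand-rolled forward/backward keeps training bit-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from .errors import ConfigurationError, TrainingError

N_ENSEMBLE_MEMBERS = 5


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters for one branch model.

    Branch defaults: properties branch uses hidden [12,12], keep 0.5,
    lr 1e-3; profile branch uses hidden [25,25], keep 0.7, lr 1e-4.
    """

    input_dim: int
    hidden_sizes: tuple[int, int] = (12, 12)
    dropout_keep: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 128
    seed: int = 0
    inverted_dropout: bool = True

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ConfigurationError("input_dim must be >= 1")
        if len(self.hidden_sizes) != 2 or any(h < 1 for h in self.hidden_sizes):
            raise ConfigurationError("hidden_sizes must be two integers >= 1")
        if not (0.0 < self.dropout_keep <= 1.0):
            raise ConfigurationError("dropout_keep must be in (0, 1]")
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MLPConfig":
        d = dict(d)
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)


def properties_config(input_dim: int = 48, **overrides) -> MLPConfig:
    base = dict(input_dim=input_dim, hidden_sizes=(12, 12),
                dropout_keep=0.5, learning_rate=1e-3)
    base.update(overrides)
    return MLPConfig(**base)


def profile_config(input_dim: int = 60, **overrides) -> MLPConfig:
    base = dict(input_dim=input_dim, hidden_sizes=(25, 25),
                dropout_keep=0.7, learning_rate=1e-4)
    base.update(overrides)
    return MLPConfig(**base)


@dataclass
class MLPParams:
    """Weights and biases of one member: input → h1 → h2 → 1."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        d, h1, h2 = self.w1.shape[1], self.w1.shape[0], self.w2.shape[0]
        ok = (self.b1.shape == (h1,) and self.w2.shape == (h2, h1)
              and self.b2.shape == (h2,) and self.w3.shape == (1, h2)
              and self.b3.shape == (1,))
        if not ok:
            raise ConfigurationError("MLP parameter shapes do not chain")

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in ("w1", "b1", "w2", "b2", "w3", "b3")}

    @classmethod
    def from_dict(cls, d: dict) -> "MLPParams":
        return cls(**{k: np.asarray(d[k], dtype=float) for k in
                      ("w1", "b1", "w2", "b2", "w3", "b3")})


@dataclass
class EnsembleModel:
    """Five trained members plus the feature standardizer fitted at training."""

    members: list[MLPParams]
    mean: np.ndarray
    std: np.ndarray
    config: MLPConfig

    def __post_init__(self) -> None:
        if len(self.members) != N_ENSEMBLE_MEMBERS:
            raise ConfigurationError(
                f"ensemble requires exactly {N_ENSEMBLE_MEMBERS} members"
            )
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (self.config.input_dim,) or self.std.shape != self.mean.shape:
            raise ConfigurationError("standardizer dimensions do not match input_dim")

    def standardize(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.config.input_dim:
            raise ConfigurationError(
                f"expected features with {self.config.input_dim} columns, "
                f"got shape {features.shape}"
            )
        return (features - self.mean) / self.std


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(params: MLPParams, features: np.ndarray, mode: str = "eval",
            keep: float = 1.0, rng: np.random.Generator | None = None,
            inverted: bool = True) -> np.ndarray:
    """Score each row of *features* (already standardized) in [0, 1].

    mode="train" applies a Bernoulli(keep) mask to each hidden activation
    (scaled by 1/keep when *inverted*); mode="eval" applies no mask.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != params.w1.shape[1]:
        raise ConfigurationError(
            f"feature dimension {x.shape} incompatible with weights "
            f"{params.w1.shape}"
        )
    if mode not in ("train", "eval"):
        raise ConfigurationError(f"unknown forward mode {mode!r}")
    if mode == "train" and rng is None:
        raise ConfigurationError("train-mode forward requires an rng")
    a1 = np.maximum(0.0, x @ params.w1.T + params.b1)
    if mode == "train":
        mask = rng.random(a1.shape) < keep
        a1 = a1 * mask / (keep if inverted else 1.0)
    a2 = np.maximum(0.0, a1 @ params.w2.T + params.b2)
    if mode == "train":
        mask = rng.random(a2.shape) < keep
        a2 = a2 * mask / (keep if inverted else 1.0)
    return _sigmoid(a2 @ params.w3.T + params.b3)[:, 0]


def balanced_subsample(features: np.ndarray, labels: np.ndarray,
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """All positives plus an equal-size random sample of negatives, shuffled."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if pos_idx.size == 0:
        raise TrainingError("no positive residues in the training data")
    if neg_idx.size == 0:
        raise TrainingError("no negative residues in the training data")
    rng = np.random.default_rng(seed)
    n_neg = min(neg_idx.size, pos_idx.size)
    sampled_neg = rng.choice(neg_idx, size=n_neg, replace=False)
    idx = np.concatenate([pos_idx, sampled_neg])
    rng.shuffle(idx)
    return features[idx], labels[idx]


def _init_params(config: MLPConfig, rng: np.random.Generator) -> MLPParams:
    # He-style scaled-uniform init, suited to ReLU units
    def layer(fan_out: int, fan_in: int) -> np.ndarray:
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    h1, h2 = config.hidden_sizes
    return MLPParams(
        w1=layer(h1, config.input_dim), b1=np.zeros(h1),
        w2=layer(h2, h1), b2=np.zeros(h2),
        w3=layer(1, h2), b3=np.zeros(1),
    )


class _Adam:
    def __init__(self, params: MLPParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(getattr(params, k)) for k in
                  ("w1", "b1", "w2", "b2", "w3", "b3")}
        self.v = {k: np.zeros_like(getattr(params, k)) for k in self.m}

    def step(self, params: MLPParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            setattr(params, k,
                    getattr(params, k) - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))


def _train_one(x: np.ndarray, y: np.ndarray, config: MLPConfig,
               seed: int) -> MLPParams:
    rng = np.random.default_rng(seed)
    params = _init_params(config, rng)
    opt = _Adam(params, config.learning_rate)
    keep = config.dropout_keep
    inv_scale = keep if config.inverted_dropout else 1.0
    n = x.shape[0]
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = x[idx], y[idx, None]
            b = xb.shape[0]

            z1 = xb @ params.w1.T + params.b1
            a1 = np.maximum(0.0, z1)
            m1 = rng.random(a1.shape) < keep
            a1d = a1 * m1 / inv_scale
            z2 = a1d @ params.w2.T + params.b2
            a2 = np.maximum(0.0, z2)
            m2 = rng.random(a2.shape) < keep
            a2d = a2 * m2 / inv_scale
            z3 = a2d @ params.w3.T + params.b3
            a3 = _sigmoid(z3)

            eps = 1e-12
            epoch_loss -= float(np.sum(yb * np.log(a3 + eps)
                                       + (1 - yb) * np.log(1 - a3 + eps)))

            dz3 = (a3 - yb) / b
            grads = {
                "w3": dz3.T @ a2d, "b3": dz3.sum(axis=0),
            }
            da2 = (dz3 @ params.w3) * m2 / inv_scale
            dz2 = da2 * (z2 > 0)
            grads["w2"] = dz2.T @ a1d
            grads["b2"] = dz2.sum(axis=0)
            da1 = (dz2 @ params.w2) * m1 / inv_scale
            dz1 = da1 * (z1 > 0)
            grads["w1"] = dz1.T @ xb
            grads["b1"] = dz1.sum(axis=0)
            opt.step(params, grads)
        if not np.isfinite(epoch_loss):
            raise TrainingError(
                f"non-finite loss at epoch {epoch} (seed {seed}, "
                f"lr {config.learning_rate}); try a lower learning rate"
            )
    return params


def train(features: np.ndarray, labels: np.ndarray,
          config: MLPConfig) -> EnsembleModel:
    """Train a 5-member ensemble on a balanced subsample of the residues.

    The feature standardizer (per-column mean/std) is fitted on the balanced
    subsample and stored in the model; member k uses derived seed
    ``config.seed + k`` for init, dropout masks, and batch order.
    """
    x, y = balanced_subsample(features, labels, config.seed)
    if x.shape[1] != config.input_dim:
        raise ConfigurationError(
            f"features have {x.shape[1]} columns but config.input_dim is "
            f"{config.input_dim}"
        )
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std < 1e-12] = 1.0
    xs = (x - mean) / std
    yf = y.astype(float)
    members = [_train_one(xs, yf, config, config.seed + k)
               for k in range(N_ENSEMBLE_MEMBERS)]
    return EnsembleModel(members=members, mean=mean, std=std, config=config)


def predict(model: EnsembleModel, features: np.ndarray) -> np.ndarray:
    """Mean of the 5 members' eval-mode scores; one value per row, in [0,1]."""
    xs = model.standardize(features)
    scores = np.stack([forward(m, xs, mode="eval") for m in model.members])
    return scores.mean(axis=0)
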