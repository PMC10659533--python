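"""Multi-task 3-D convolutional model for progression, MMSE slope, and
hippocampal volume.

A parameter-efficient dual-branch network: each enabled image modality
(T1-like MRI intensity, Jacobian determinant) passes through a small stack
of strided separable 3-D convolution blocks; the globally pooled branch
features are concatenated with the [0, 1]-scaled clinical vector and fed
through a shared dense layer into three output heads — a sigmoid head for
4-year progression and two linear heads for MMSE slope and hippocampal
volume.  Training minimizes

    L = w1 * L1 + w2 * L2 + w3 * L3

where L1 is class-weighted binary cross-entropy on progression and L2/L3
are mean-squared errors on the [0, 1]-scaled regression targets.  The
default weighting for the progression task is ``w1 = 1, w2 = w3 = 0.025``;
for the slope task ``w2 = 1, w1 = w3 = 0.025``.

Implemented in NumPy (see :mod:`neuroprog.nn`); training is deterministic
given the seed.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, NeuroprogError
from .nn import Adam, Conv3d, Dense, GlobalAvgPool3d, ReLU, Sequential, sigmoid

__all__ = [
    "LossWeights",
    "ArchConfig",
    "TrainingSchedule",
    "DeepDataset",
    "DeepOutputs",
    "MultiTaskCNN",
    "build_network",
    "combine_losses",
    "multitask_loss",
    "train_deep",
    "grid_search_weights",
    "PROGRESSION_WEIGHTS",
    "SLOPE_WEIGHTS",
    "WEIGHT_GRID",
]

#: Auxiliary-weight grid searched on validation data (0 disables multi-task
#: learning; the top value is 0.1).
WEIGHT_GRID = (0.0, 0.025, 0.05, 0.075, 0.1)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the three task losses (progression, slope, hippocampus)."""

    w1: float = 1.0
    w2: float = 0.025
    w3: float = 0.025

    def validate(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ConfigurationError(f"loss weights must be non-negative, got {self}")
        if self.w1 == self.w2 == self.w3 == 0:
            raise ConfigurationError("at least one loss weight must be positive")


PROGRESSION_WEIGHTS = LossWeights(1.0, 0.025, 0.025)
SLOPE_WEIGHTS = LossWeights(0.025, 1.0, 0.025)


@dataclass(frozen=True)
class ArchConfig:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_clinical: int = 6
    channels: tuple[int, int, int] = (8, 16, 32)
    hidden: int = 32
    use_mri: bool = True
    use_jd: bool = True
    seed: int = 0

    @property
    def n_stages(self) -> int:
        return 3

    def validate(self) -> None:
        if not (self.use_mri or self.use_jd):
            raise ConfigurationError("at least one of use_mri / use_jd must be true")
        minimum = 2 ** self.n_stages
        if any(n < minimum for n in self.grid_shape):
            raise ConfigurationError(
                f"grid {self.grid_shape} too small for {self.n_stages} "
                f"downsampling stages; minimal admissible shape is "
                f"({minimum}, {minimum}, {minimum})"
            )
        if self.n_clinical < 0:
            raise ConfigurationError("n_clinical must be >= 0")


@dataclass(frozen=True)
class TrainingSchedule:
    epochs: int = 50
    batch_size: int = 32
    lr0: float = 1e-3
    lr_decay: float = 0.97  # multiplicative per-epoch decay


@dataclass
class DeepDataset:
    """Preprocessed network inputs: volumes normalized per the preprocessing
    contract (MRI in [-1, 1], JD raw), clinical features in [0, 1], and the
    regression targets min-max scaled on the training fold.  Missing slope
    targets are NaN and masked out of L2."""

    clinical: np.ndarray  # (N, F) in [0, 1]
    y_progression: np.ndarray  # (N,) in {0, 1}
    y_slope: np.ndarray  # (N,) scaled to [0, 1]; NaN = missing
    y_hippocampus: np.ndarray  # (N,) scaled to [0, 1]
    mri: np.ndarray | None = None  # (N, 1, D, H, W)
    jd: np.ndarray | None = None
    subject_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.clinical.shape[0]

    def take(self, idx) -> "DeepDataset":
        return DeepDataset(
            clinical=self.clinical[idx],
            y_progression=self.y_progression[idx],
            y_slope=self.y_slope[idx],
            y_hippocampus=self.y_hippocampus[idx],
            mri=None if self.mri is None else self.mri[idx],
            jd=None if self.jd is None else self.jd[idx],
            subject_ids=[self.subject_ids[i] for i in np.atleast_1d(idx)]
            if self.subject_ids else [],
        )


@dataclass
class DeepOutputs:
    p_progression: np.ndarray  # strictly inside (0, 1)
    mmse_slope_hat: np.ndarray
    hippocampal_volume_hat: np.ndarray


def _branch(c: Sequence[int], rng: np.random.Generator) -> Sequential:
    c0, c1, c2 = c
    return Sequential(
        Conv3d(1, c0, kernel=3, stride=2, padding=1, rng=rng), ReLU(),
        Conv3d(c0, c0, kernel=3, stride=2, padding=1, groups=c0, rng=rng),
        Conv3d(c0, c1, kernel=1, rng=rng), ReLU(),
        Conv3d(c1, c1, kernel=3, stride=2, padding=1, groups=c1, rng=rng),
        Conv3d(c1, c2, kernel=1, rng=rng), ReLU(),
        GlobalAvgPool3d(),
    )


class MultiTaskCNN:
    """The three-headed network.  See the module docstring."""

    def __init__(self, arch: ArchConfig):
        arch.validate()
        self.arch = arch
        rng = np.random.default_rng(arch.seed)
        self.branches: dict[str, Sequential] = {}
        if arch.use_mri:
            self.branches["mri"] = _branch(arch.channels, rng)
        if arch.use_jd:
            self.branches["jd"] = _branch(arch.channels, rng)
        feat = arch.channels[-1] * len(self.branches) + arch.n_clinical
        self.trunk = Sequential(Dense(feat, arch.hidden, rng=rng), ReLU())
        self.head_progression = Dense(arch.hidden, 1, rng=rng)
        self.head_slope = Dense(arch.hidden, 1, rng=rng)
        self.head_hippocampus = Dense(arch.hidden, 1, rng=rng)

    # -- plumbing --------------------------------------------------------
    def _modules(self):
        return list(self.branches.values()) + [
            self.trunk, self.head_progression, self.head_slope, self.head_hippocampus]

    def parameters(self) -> list[np.ndarray]:
        return [p for m in self._modules() for p in m.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for m in self._modules() for g in m.gradients()]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def save(self, path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path) -> "MultiTaskCNN":
        return pickle.loads(Path(path).read_bytes())

    # -- forward / backward ---------------------------------------------
    def _inputs(self, data: DeepDataset) -> dict[str, np.ndarray]:
        out = {}
        for name in self.branches:
            x = getattr(data, name)
            if x is None:
                raise DataError(f"network requires the {name!r} channel but the "
                                "dataset does not provide it")
            out[name] = np.asarray(x, dtype=float)
        return out

    def forward_logits(self, data: DeepDataset, train: bool = False):
        feats = [self.branches[k].forward(v, train=train)
                 for k, v in self._inputs(data).items()]
        feats.append(np.asarray(data.clinical, dtype=float))
        x = np.concatenate(feats, axis=1)
        self._n_branch_feats = [f.shape[1] for f in feats]
        h = self.trunk.forward(x, train=train)
        return (self.head_progression.forward(h, train=train)[:, 0],
                self.head_slope.forward(h, train=train)[:, 0],
                self.head_hippocampus.forward(h, train=train)[:, 0])

    def backward(self, dz1, dz2, dz3) -> None:
        dh = (self.head_progression.backward(dz1[:, None])
              + self.head_slope.backward(dz2[:, None])
              + self.head_hippocampus.backward(dz3[:, None]))
        dx = self.trunk.backward(dh)
        start = 0
        for name, width in zip(self.branches, self._n_branch_feats):
            self.branches[name].backward(dx[:, start:start + width])
            start += width

    def predict(self, data: DeepDataset) -> DeepOutputs:
        z1, z2, z3 = self.forward_logits(data, train=False)
        p = np.clip(sigmoid(z1), 1e-12, 1.0 - 1e-12)
        return DeepOutputs(p_progression=p, mmse_slope_hat=z2, hippocampal_volume_hat=z3)


def build_network(arch: ArchConfig) -> MultiTaskCNN:
    """Instantiate the network with deterministic seed-driven initialization."""
    return MultiTaskCNN(arch)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def combine_losses(l1: float, l2: float, l3: float, weights: LossWeights) -> float:
    """The weighted total loss L = w1*L1 + w2*L2 + w3*L3."""
    weights.validate()
    return weights.w1 * l1 + weights.w2 * l2 + weights.w3 * l3


def _task_losses(z1, z2, z3, data: DeepDataset, class_weights) -> tuple[float, float, float]:
    y = np.asarray(data.y_progression, dtype=float)
    w = np.where(y == 1, class_weights.get(1, 1.0), class_weights.get(0, 1.0))
    # numerically stable BCE with logits: softplus(z) - y*z  (+ z clamp-free)
    with np.errstate(invalid="ignore"):  # NaN inputs surface as NaN loss
        bce = np.logaddexp(0.0, z1) - y * z1
    l1 = float(np.mean(w * bce))
    l2 = _masked_mse(z2, data.y_slope)
    l3 = _masked_mse(z3, data.y_hippocampus)
    return l1, l2, l3


def _masked_mse(pred, target) -> float:
    t = np.asarray(target, dtype=float)
    mask = np.isfinite(t)
    if not mask.any():
        return 0.0
    e = pred[mask] - t[mask]
    return float(np.mean(e * e))


def multitask_loss(outputs: DeepOutputs, data: DeepDataset, weights: LossWeights,
                   class_weights: dict | None = None) -> float:
    """Evaluate L = w1*L1 + w2*L2 + w3*L3 on predicted outputs.

    L1 is class-weighted binary cross-entropy on the progression
    probability; L2/L3 are MSE on the scaled regression targets (NaN
    targets masked out).
    """
    weights.validate()
    class_weights = class_weights or {}
    p = np.clip(outputs.p_progression, 1e-12, 1 - 1e-12)
    if not np.all(np.isfinite(p)):
        raise DataError("non-finite progression outputs")
    y = np.asarray(data.y_progression, dtype=float)
    w = np.where(y == 1, class_weights.get(1, 1.0), class_weights.get(0, 1.0))
    l1 = float(np.mean(-w * (y * np.log(p) + (1 - y) * np.log1p(-p))))
    l2 = _masked_mse(outputs.mmse_slope_hat, data.y_slope)
    l3 = _masked_mse(outputs.hippocampal_volume_hat, data.y_hippocampus)
    return combine_losses(l1, l2, l3, weights)


def class_weights_from_labels(y) -> dict[int, float]:
    """Inverse-frequency class weights: w_c = N / (2 * N_c)."""
    y = np.asarray(y).astype(int)
    n = y.size
    return {c: n / (2.0 * max(1, int(np.sum(y == c)))) for c in (0, 1)}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_deep(
    network: MultiTaskCNN,
    train_data: DeepDataset,
    val_data: DeepDataset | None = None,
    schedule: TrainingSchedule = TrainingSchedule(),
    weights: LossWeights = PROGRESSION_WEIGHTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Mini-batch Adam training of the three-task loss.

    Returns the per-epoch history (train/val loss per task and total).  A
    schedule with ``epochs=0`` leaves the network untouched.  The learning
    rate decays multiplicatively per epoch.  A non-finite loss aborts with a
    diagnostic naming the epoch and batch.
    """
    weights.validate()
    if len(train_data) == 0:
        raise DataError("empty training set")
    cw = class_weights_from_labels(train_data.y_progression)
    opt = Adam(network.parameters(), network.gradients(), lr=schedule.lr0)
    rng = np.random.default_rng(seed)
    history = []
    n = len(train_data)
    for epoch in range(schedule.epochs):
        opt.lr = schedule.lr0 * schedule.lr_decay**epoch
        order = rng.permutation(n)
        ep = {"l1": 0.0, "l2": 0.0, "l3": 0.0}
        for bi, start in enumerate(range(0, n, schedule.batch_size)):
            batch = train_data.take(order[start:start + schedule.batch_size])
            m = len(batch)
            z1, z2, z3 = network.forward_logits(batch, train=True)
            l1, l2, l3 = _task_losses(z1, z2, z3, batch, cw)
            total = combine_losses(l1, l2, l3, weights)
            if not np.isfinite(total):
                raise NeuroprogError(
                    f"non-finite loss at epoch {epoch}, batch {bi} "
                    f"(L1={l1}, L2={l2}, L3={l3})")
            # gradients of the mean losses w.r.t. head outputs
            y = batch.y_progression.astype(float)
            wv = np.where(y == 1, cw[1], cw[0])
            dz1 = weights.w1 * wv * (sigmoid(z1) - y) / m
            dz2 = weights.w2 * _masked_mse_grad(z2, batch.y_slope)
            dz3 = weights.w3 * _masked_mse_grad(z3, batch.y_hippocampus)
            opt.zero_grad()
            network.backward(dz1, dz2, dz3)
            opt.step()
            frac = m / n
            ep["l1"] += l1 * frac
            ep["l2"] += l2 * frac
            ep["l3"] += l3 * frac
        row = {"epoch": epoch, "lr": opt.lr,
               "train_l1": ep["l1"], "train_l2": ep["l2"], "train_l3": ep["l3"],
               "train_total": combine_losses(ep["l1"], ep["l2"], ep["l3"], weights)}
        if val_data is not None and len(val_data):
            z1, z2, z3 = network.forward_logits(val_data, train=False)
            v1, v2, v3 = _task_losses(z1, z2, z3, val_data, cw)
            row.update(val_l1=v1, val_l2=v2, val_l3=v3,
                       val_total=combine_losses(v1, v2, v3, weights))
        history.append(row)
    return pd.DataFrame(history)


def _masked_mse_grad(pred, target) -> np.ndarray:
    t = np.asarray(target, dtype=float)
    mask = np.isfinite(t)
    g = np.zeros_like(pred)
    if mask.any():
        g[mask] = 2.0 * (pred[mask] - t[mask]) / mask.sum()
    return g


# ---------------------------------------------------------------------------
# Loss-weight grid search
# ---------------------------------------------------------------------------

def grid_search_weights(
    candidates: Sequence[float],
    main_task: str,
    fold_datasets: Sequence[tuple[DeepDataset, DeepDataset]],
    arch: ArchConfig,
    schedule: TrainingSchedule = TrainingSchedule(),
    seed: int = 0,
    metric_fn: Callable | None = None,
) -> tuple[LossWeights, pd.DataFrame]:
    """Pick the auxiliary loss weight maximizing the mean validation metric.

    The main task keeps weight 1; both auxiliary weights take the candidate
    value.  ``main_task`` is ``"progression"`` (validation AUC) or
    ``"slope"`` (validation R²).  One model is trained per candidate per
    fold.  Returns the winning :class:`LossWeights` and the score table.
    """
    from .evaluation import auc, r_squared  # local import to avoid a cycle

    if not candidates:
        raise ConfigurationError("candidate list must be non-empty")
    if main_task not in ("progression", "slope"):
        raise ConfigurationError(f"unknown main task {main_task!r}")
    rows = []
    for c in candidates:
        weights = (LossWeights(1.0, c, c) if main_task == "progression"
                   else LossWeights(c, 1.0, c))
        scores = []
        for fi, (tr, va) in enumerate(fold_datasets):
            net = build_network(replace(arch, seed=arch.seed + fi))
            train_deep(net, tr, va, schedule=schedule, weights=weights,
                       seed=seed + fi)
            out = net.predict(va)
            if metric_fn is not None:
                scores.append(metric_fn(out, va))
            elif main_task == "progression":
                scores.append(auc(out.p_progression, va.y_progression))
            else:
                mask = np.isfinite(va.y_slope)
                scores.append(r_squared(out.mmse_slope_hat[mask], va.y_slope[mask]))
        rows.append({"candidate": c, "mean_val_metric": float(np.mean(scores))})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["mean_val_metric"].idxmax(), "candidate"])
    winner = (LossWeights(1.0, best, best) if main_task == "progression"
              else LossWeights(best, 1.0, best))
    return winner, table
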