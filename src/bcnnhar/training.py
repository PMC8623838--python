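"""Training of standard and branch CNNs: multi-level loss and augmentations.

The branch-CNN loss for one sample is a weighted sum of per-level softmax
cross-entropies,

    L_i = - sum_k sum_c  w_k * t_{i,c}^k * log softmax(y_i^k)_c ,

where level k has C_k classes, y^k are that level's pre-softmax scores and
t^k is the (possibly soft) target distribution.  The level weights w_k are
non-negative and sum to one; with equal weights every hierarchy level
contributes the same share of the gradient.

Three augmentations are applied per batch, in order: RICAP (windows are
re-assembled from time segments of randomly paired batch members, and the
labels at every level become length-weighted mixtures), random permutation
of the x/y/z channels, and random per-channel sign inversion.  The last two
exploit that the device's orientation in the pocket is arbitrary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from bcnnhar.model import BCNN

logger = logging.getLogger(__name__)

__all__ = [
    "LossSpec",
    "HierLabels",
    "TrainConfig",
    "one_hot",
    "softmax",
    "bcnn_loss",
    "bcnn_loss_grad",
    "ricap_1d",
    "axis_swap",
    "amplitude_invert",
    "train",
]


@dataclass(frozen=True)
class LossSpec:
    """Per-level loss weights and class counts; weights must sum to one."""

    weights: tuple[float, ...]
    level_class_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "level_class_counts", tuple(self.level_class_counts))
        if len(self.weights) != len(self.level_class_counts):
            raise ValueError("need one weight per level")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")

    @classmethod
    def equal(cls, level_class_counts: Sequence[int]) -> "LossSpec":
        k = len(level_class_counts)
        return cls((1.0 / k,) * k, tuple(level_class_counts))


class HierLabels:
    """Per-sample labels at every hierarchy level, hard or soft.

    ``levels[k]`` is either an integer index array of shape (n,) or, after a
    mixing augmentation, a float array of shape (n, C_k) whose rows are
    probability vectors.
    """

    def __init__(self, levels: Sequence[np.ndarray], level_class_counts: Sequence[int]):
        self.levels = [np.asarray(a) for a in levels]
        self.level_class_counts = tuple(level_class_counts)
        if len(self.levels) != len(self.level_class_counts):
            raise ValueError("need one label array per level")
        n = len(self.levels[0])
        for arr, c in zip(self.levels, self.level_class_counts):
            if len(arr) != n:
                raise ValueError("level label arrays must have equal length")
            if arr.ndim == 1:
                if arr.size and (arr.min() < 0 or arr.max() >= c):
                    raise ValueError("hard label out of range")
            elif arr.ndim == 2:
                if arr.shape[1] != c:
                    raise ValueError("soft label width mismatch")
            else:
                raise ValueError("labels must be 1-D (hard) or 2-D (soft)")

    def __len__(self) -> int:
        return len(self.levels[0])

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def to_soft(self) -> list[np.ndarray]:
        """One-hot encode any hard level; soft levels pass through."""
        out = []
        for arr, c in zip(self.levels, self.level_class_counts):
            if arr.ndim == 1:
                out.append(np.eye(c, dtype=np.float64)[arr])
            else:
                out.append(np.asarray(arr, dtype=np.float64))
        return out

    def take(self, idx: np.ndarray) -> "HierLabels":
        return HierLabels([a[idx] for a in self.levels], self.level_class_counts)


@dataclass
class TrainConfig:
    """Optimization and augmentation settings.

    Defaults follow the benchmark protocol: Adam at learning rate 0.001,
    300 epochs for branch models (200 for the plain std model used in
    hierarchy construction), RICAP beta 0.5, and all three augmentations
    on.  Batch size is not part of the protocol; 64 is the default.
    """

    learning_rate: float = 0.001
    epochs: int = 300
    batch_size: int = 64
    ricap: bool = True
    ricap_beta: float = 0.5
    ricap_segments: int = 2
    axis_swap: bool = True
    amplitude_invert: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if self.ricap_segments not in (2, 4):
            raise ValueError("ricap_segments must be 2 or 4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def one_hot(label: int, n_classes: int) -> np.ndarray:
    if not 0 <= label < n_classes:
        raise IndexError(f"label {label} out of range for {n_classes} classes")
    v = np.zeros(n_classes)
    v[label] = 1.0
    return v


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _log_softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def _per_level_ce(scores: list[np.ndarray], soft: list[np.ndarray]) -> np.ndarray:
    return np.array(
        [-(t * _log_softmax(np.asarray(y, dtype=np.float64))).sum(axis=1).mean()
         for y, t in zip(scores, soft)]
    )


def bcnn_loss(scores: Sequence[np.ndarray], targets: HierLabels, spec: LossSpec) -> float:
    """Batch-mean weighted multi-level cross-entropy; accepts soft targets."""
    scores = [np.atleast_2d(s) for s in scores]
    if len(scores) != len(spec.weights) or targets.n_levels != len(spec.weights):
        raise ValueError("scores, targets and spec must agree on the number of levels")
    for s, c in zip(scores, spec.level_class_counts):
        if s.shape[1] != c:
            raise ValueError(f"score width {s.shape[1]} != class count {c}")
    level_ce = _per_level_ce(scores, targets.to_soft())
    return float(np.dot(spec.weights, level_ce))


def bcnn_loss_grad(
    scores: Sequence[np.ndarray], targets: HierLabels, spec: LossSpec
) -> list[np.ndarray]:
    """Analytic gradient of :func:`bcnn_loss` w.r.t. each level's scores."""
    soft = targets.to_soft()
    n = len(targets)
    return [
        (w * (softmax(np.asarray(y, dtype=np.float64)) - t) / n).astype(np.float32)
        for w, y, t in zip(spec.weights, scores, soft)
    ]


def _segment_fractions(beta: float, n_segments: int, rng: np.random.Generator) -> np.ndarray:
    """Segment length fractions: one Beta(beta, beta) cut, refined once for 4 segments."""
    f = rng.beta(beta, beta)
    if n_segments == 2:
        return np.array([f, 1.0 - f])
    g1, g2 = rng.beta(beta, beta), rng.beta(beta, beta)
    return np.array([f * g1, f * (1 - g1), (1 - f) * g2, (1 - f) * (1 - g2)])


def ricap_1d(
    batch: np.ndarray,
    hier_labels: HierLabels,
    rng: np.random.Generator,
    beta: float = 0.5,
    n_segments: int = 2,
) -> tuple[np.ndarray, HierLabels]:
    """Random time-axis crop-and-patch: windows assembled from segments of peers.

    Segment boundaries are drawn once per batch from Beta(beta, beta); each
    segment's content comes from an independently permuted copy of the
    batch.  Labels at every hierarchy level become mixtures of the sources'
    one-hot labels, weighted by segment length.  Window length is preserved.
    """
    batch = np.asarray(batch)
    n, t = batch.shape[0], batch.shape[1]
    if n < 2:
        logger.warning("RICAP skipped: batch of %d has no partner to mix with", n)
        return batch, hier_labels

    fractions = _segment_fractions(beta, n_segments, rng)
    lengths = np.floor(fractions * t).astype(int)
    lengths[-1] = t - lengths[:-1].sum()
    weights = lengths / t

    sources = [np.arange(n)] + [rng.permutation(n) for _ in range(n_segments - 1)]
    pieces, soft_levels = [], None
    pos = 0
    for seg, (src, length) in enumerate(zip(sources, lengths)):
        pieces.append(batch[src, pos : pos + length])
        pos += length
    mixed = np.concatenate(pieces, axis=1)

    soft = hier_labels.to_soft()
    out_levels = []
    for level in soft:
        acc = np.zeros_like(level)
        for src, w in zip(sources, weights):
            acc += w * level[src]
        out_levels.append(acc)
    return mixed, HierLabels(out_levels, hier_labels.level_class_counts)


def axis_swap(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute the x/y/z channels of each window independently and uniformly."""
    batch = np.asarray(batch)
    perms = np.array([[0, 1, 2], [0, 2, 1], [1, 0, 2], [1, 2, 0], [2, 0, 1], [2, 1, 0]])
    choice = rng.integers(0, 6, size=len(batch))
    return np.take_along_axis(batch, perms[choice][:, None, :], axis=2)


def amplitude_invert(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip the sign of each channel of each window with probability 1/2."""
    batch = np.asarray(batch)
    signs = rng.choice([-1.0, 1.0], size=(len(batch), 1, batch.shape[2]))
    return batch * signs.astype(batch.dtype)


def augment_batch(
    batch: np.ndarray, labels: HierLabels, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[np.ndarray, HierLabels]:
    if cfg.ricap:
        batch, labels = ricap_1d(batch, labels, rng, cfg.ricap_beta, cfg.ricap_segments)
    if cfg.axis_swap:
        batch = axis_swap(batch, rng)
    if cfg.amplitude_invert:
        batch = amplitude_invert(batch, rng)
    return batch, labels


def train(
    model: BCNN,
    windows: np.ndarray,
    hier_labels: HierLabels,
    cfg: TrainConfig,
    loss_spec: LossSpec | None = None,
) -> pd.DataFrame:
    """Minibatch Adam training of a (branch) CNN; returns the loss history.

    Augmentations run per batch in the order RICAP, axis swap, amplitude
    inversion.  The history has one row per epoch with the total loss and
    each level's unweighted cross-entropy.  Raises on NaN loss.
    """
    from bcnnhar import nn

    windows = np.asarray(windows, dtype=np.float32)
    if len(windows) == 0:
        raise ValueError("cannot train on an empty dataset")
    if hier_labels.n_levels != model.n_levels:
        raise ValueError(
            f"labels have {hier_labels.n_levels} levels but model has {model.n_levels}"
        )
    loss_spec = loss_spec or LossSpec.equal(model.branch.level_class_counts)
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(model.params, lr=cfg.learning_rate)

    n = len(windows)
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_total = 0.0
        epoch_levels = np.zeros(model.n_levels)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = augment_batch(windows[idx], hier_labels.take(idx), cfg, rng)
            scores = model.forward(xb, train=True)
            level_ce = _per_level_ce(scores, yb.to_soft())
            total = float(np.dot(loss_spec.weights, level_ce))
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss {total} at epoch {epoch}, batch {n_batches}; "
                    "consider lowering the learning rate"
                )
            optimizer.zero_grad()
            model.backward(bcnn_loss_grad(scores, yb, loss_spec))
            optimizer.step()
            epoch_total += total
            epoch_levels += level_ce
            n_batches += 1
        row = {"epoch": epoch, "loss": epoch_total / n_batches}
        for k in range(model.n_levels):
            row[f"level{k + 1}_ce"] = epoch_levels[k] / n_batches
        rows.append(row)
    return pd.DataFrame(rows)
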