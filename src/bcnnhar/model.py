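"""The branch 1D CNN: a VGG-style backbone with classifier heads at branch points.

A branch CNN (B-CNN) is a plain convolutional backbone of Conv Blocks (a
few length-preserving 1D convolutions followed by max pooling) with one
classifier head per hierarchy level.  Coarse-level heads attach after
intermediate blocks; the target-level head sits after the last block.
Every head is a global average pooling over time followed by a single
fully connected layer, so heads are cheap and length-agnostic.  Levels are
predicted independently — the model never forces a fine prediction to be
consistent with the coarse head's output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from bcnnhar import nn

__all__ = [
    "ConvBlockSpec",
    "BackboneSpec",
    "BranchSpec",
    "BCNN",
    "vgg16_1d_backbone",
    "tiny_backbone",
    "build_bcnn",
]


@dataclass(frozen=True)
class ConvBlockSpec:
    """One Conv Block: ``n_conv`` convolutions of ``filters`` channels, then pooling."""

    n_conv: int
    filters: int
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.n_conv < 1 or self.filters < 1 or self.kernel < 1:
            raise ValueError("n_conv, filters and kernel must be >= 1")


@dataclass(frozen=True)
class BackboneSpec:
    blocks: tuple[ConvBlockSpec, ...]
    pool: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValueError("backbone needs at least one block")
        if self.pool < 2:
            raise ValueError("pool factor must be >= 2")


@dataclass(frozen=True)
class BranchSpec:
    """Where coarse heads attach and how many classes each level has.

    ``positions`` are 1-based block indices: coarse head j attaches after
    block ``positions[j]``.  ``level_class_counts`` lists C_1 ... C_K from
    the coarsest level down to the target level, so
    ``len(positions) == K - 1``.  An empty ``positions`` describes the plain
    single-head CNN (the "std" model).
    """

    positions: tuple[int, ...]
    level_class_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        object.__setattr__(self, "level_class_counts", tuple(self.level_class_counts))
        if len(self.positions) != len(self.level_class_counts) - 1:
            raise ValueError("need exactly one class count per coarse level plus the target")
        if any(c < 1 for c in self.level_class_counts):
            raise ValueError("class counts must be >= 1")
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("branch positions must be strictly increasing")
        if self.positions and self.positions[0] < 1:
            raise ValueError("branch positions are 1-based")

    @property
    def n_levels(self) -> int:
        return len(self.level_class_counts)


def vgg16_1d_backbone(width_multiplier: float = 1.0, kernel: int = 3) -> BackboneSpec:
    """The VGG16 layout adapted to 1D: (2,2,3,3,3) convs, (64,128,256,512,512) filters.

    ``width_multiplier`` scales every filter count: 0.5 gives the halved
    "VGG16-S" variant, 2.0 the doubled "VGG16-W".
    """
    if width_multiplier <= 0:
        raise ValueError("width_multiplier must be positive")
    layout = [(2, 64), (2, 128), (3, 256), (3, 512), (3, 512)]
    blocks = [
        ConvBlockSpec(n, max(1, int(round(f * width_multiplier))), kernel) for n, f in layout
    ]
    return BackboneSpec(tuple(blocks))


def tiny_backbone(filters: Sequence[int] = (8, 16), kernel: int = 3) -> BackboneSpec:
    """A two-block, single-conv-per-block backbone for CPU-scale experiments."""
    return BackboneSpec(tuple(ConvBlockSpec(1, f, kernel) for f in filters))


class _Head:
    """Classifier head: global average pooling + one fully connected layer.

    The head is zero-initialized so every model starts from the uniform
    predictor (initial loss log C_k per level) regardless of the raw
    feature scale; gradients through a zero linear head are still nonzero.
    """

    def __init__(self, in_features: int, n_classes: int, rng: np.random.Generator):
        self.gap = nn.GlobalAvgPool1d()
        self.fc = nn.Dense(in_features, n_classes, rng)
        self.fc.weight.value[...] = 0.0

    @property
    def params(self) -> list[nn.Param]:
        return self.fc.params

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.fc.forward(self.gap.forward(x, train), train)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        return self.gap.backward(self.fc.backward(dscores))


class BCNN:
    """Branch CNN over (batch, window, 3) inputs; K score vectors per sample.

    ``forward`` returns a list of K (batch, C_k) pre-softmax score arrays,
    coarsest level first.  ``backward`` takes the matching list of score
    gradients and accumulates parameter gradients, summing trunk gradients
    at each branch point.
    """

    def __init__(
        self,
        backbone: BackboneSpec,
        branch: BranchSpec,
        input_shape: tuple[int, int] = (256, 3),
        seed: int = 0,
    ):
        n_blocks = len(backbone.blocks)
        if branch.positions and branch.positions[-1] >= n_blocks:
            raise ValueError(
                f"branch position {branch.positions[-1]} out of range for {n_blocks} blocks"
            )
        self.backbone = backbone
        self.branch = branch
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.blocks: list[list] = []
        in_ch = input_shape[1]
        block_channels = []
        for spec in backbone.blocks:
            layers: list = []
            for _ in range(spec.n_conv):
                layers.append(nn.Conv1d(in_ch, spec.filters, spec.kernel, rng))
                layers.append(nn.ReLU())
                in_ch = spec.filters
            layers.append(nn.MaxPool1d(backbone.pool))
            self.blocks.append(layers)
            block_channels.append(spec.filters)

        # head k sits after block head_positions[k]; target head after the last block
        self.head_positions = list(branch.positions) + [n_blocks]
        self.heads = [
            _Head(block_channels[pos - 1], c, rng)
            for pos, c in zip(self.head_positions, branch.level_class_counts)
        ]

    @property
    def n_levels(self) -> int:
        return self.branch.n_levels

    @property
    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for layers in self.blocks:
            for layer in layers:
                out.extend(layer.params)
        for head in self.heads:
            out.extend(head.params)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(f"expected batch of shape (B, {self.input_shape}), got {x.shape}")
        h = x.transpose(0, 2, 1)  # (B, channels, time)
        block_out = []
        for layers in self.blocks:
            for layer in layers:
                h = layer.forward(h, train)
            block_out.append(h)
        return [
            head.forward(block_out[pos - 1], train)
            for head, pos in zip(self.heads, self.head_positions)
        ]

    def backward(self, dscores: list[np.ndarray]) -> None:
        n_blocks = len(self.blocks)
        pending: dict[int, np.ndarray] = {}
        for head, pos, ds in zip(self.heads, self.head_positions, dscores):
            g = head.backward(np.asarray(ds, dtype=np.float32))
            pending[pos] = pending.get(pos, 0.0) + g
        d = None
        for bi in range(n_blocks, 0, -1):
            if bi in pending:
                d = pending[bi] if d is None else d + pending[bi]
            for layer in reversed(self.blocks[bi - 1]):
                d = layer.backward(d)

    def extract_features(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Penultimate representation: post-GAP activations of the final block."""
        x = np.asarray(x, dtype=np.float32)
        feats = []
        for start in range(0, len(x), batch_size):
            h = x[start : start + batch_size].transpose(0, 2, 1)
            for layers in self.blocks:
                for layer in layers:
                    h = layer.forward(h, train=False)
            feats.append(h.mean(axis=2))
        return np.concatenate(feats)

    # --- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Framework-native weights (.npz) plus a JSON sidecar of the specs."""
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params)}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "backbone": {
                "blocks": [
                    {"n_conv": b.n_conv, "filters": b.filters, "kernel": b.kernel}
                    for b in self.backbone.blocks
                ],
                "pool": self.backbone.pool,
            },
            "branch": {
                "positions": list(self.branch.positions),
                "level_class_counts": list(self.branch.level_class_counts),
            },
            "input_shape": list(self.input_shape),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BCNN":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        backbone = BackboneSpec(
            tuple(ConvBlockSpec(**b) for b in sidecar["backbone"]["blocks"]),
            sidecar["backbone"]["pool"],
        )
        branch = BranchSpec(
            tuple(sidecar["branch"]["positions"]),
            tuple(sidecar["branch"]["level_class_counts"]),
        )
        model = cls(backbone, branch, tuple(sidecar["input_shape"]), sidecar["seed"])
        arrays = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params):
            p.value[...] = arrays[f"p{i}"]
        return model


def build_bcnn(
    backbone: BackboneSpec,
    branch: BranchSpec,
    input_shape: tuple[int, int] = (256, 3),
    seed: int = 0,
) -> BCNN:
    """Construct a branch CNN; with no branch positions this is the plain std model."""
    return BCNN(backbone, branch, input_shape, seed)
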