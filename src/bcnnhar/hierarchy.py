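"""Automatic construction of class hierarchies from training data.

The hierarchy is built bottom-up from the geometry of the classes in a
learned feature space:

1. split the training set into a pre-training half and an adaptation half;
2. train a plain (single-head) CNN on the pre-training half;
3. push the adaptation half through the trained CNN and keep the
   penultimate (post global-average-pooling) activations;
4. reduce the features with PCA;
5. average the reduced features per target class to get class centroids;
6. cluster the centroids with Ward linkage into a dendrogram;
7. find the largest gaps between consecutive merge heights — a large gap
   marks a natural number of clusters — and cut the dendrogram just above
   the lower height of each selected gap.

Each cut yields one coarse level; because all levels are horizontal cuts of
the same dendrogram, the resulting partitions are automatically nested
(coarser levels merge whole blocks of finer levels).  The nesting property
is still validated on every constructed hierarchy, and also on hierarchies
supplied by hand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split

from bcnnhar.model import BackboneSpec, BranchSpec, build_bcnn, vgg16_1d_backbone
from bcnnhar.sensor_data import WindowedDataset
from bcnnhar.training import HierLabels, TrainConfig, train

logger = logging.getLogger(__name__)

__all__ = [
    "HierarchyBuildConfig",
    "FeatureMatrix",
    "CentroidSet",
    "Dendrogram",
    "HierarchicalLabelSet",
    "split_for_hierarchy",
    "extract_features",
    "reduce_pca",
    "class_centroids",
    "ward_dendrogram",
    "gap_thresholds",
    "flat_clusters",
    "relabel",
    "build_hierarchy",
]


@dataclass(frozen=True)
class HierarchyBuildConfig:
    """Parameters of the hierarchy-construction pipeline.

    ``r_pre`` is the fraction of the training set used to pre-train the
    plain CNN (default 0.5); ``d`` the PCA output dimension (default 64,
    clamped when fewer samples or features are available); ``n_coarse_levels``
    the number of coarse levels L to cut; ``epsilon`` the offset added to a
    selected merge height to place the threshold just above it (default
    1e-6 of the height range).  ``backbone`` and ``train_cfg`` control the
    plain CNN; the protocol default is the full 1D VGG16 trained for 200
    epochs, which tests replace with a tiny backbone and few epochs.
    """

    r_pre: float = 0.5
    d: int = 64
    n_coarse_levels: int = 2
    epsilon: float | None = None
    seed: int = 0
    backbone: BackboneSpec | None = None
    train_cfg: TrainConfig | None = None

    def __post_init__(self) -> None:
        if not 0 < self.r_pre < 1:
            raise ValueError("r_pre must be in (0, 1)")
        if self.d < 1 or self.n_coarse_levels < 1:
            raise ValueError("d and n_coarse_levels must be >= 1")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class FeatureMatrix:
    """Rows of per-window features with their target labels."""

    F: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.F.ndim != 2 or len(self.F) != len(self.labels):
            raise ValueError("F must be 2-D with one label per row")
        if not np.isfinite(self.F).all():
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class CentroidSet:
    """Per-class arithmetic mean of feature rows, ordered by class index."""

    F_center: np.ndarray

    def __post_init__(self) -> None:
        self.F_center = np.asarray(self.F_center, dtype=np.float64)
        if self.F_center.ndim != 2:
            raise ValueError("F_center must be (C, d)")
        if not np.isfinite(self.F_center).all():
            raise ValueError("centroids contain non-finite values")

    @property
    def n_classes(self) -> int:
        return self.F_center.shape[0]


@dataclass
class Dendrogram:
    """Ward merge record: scipy linkage matrix with monotone heights.

    Merge i joins clusters ``Z[i, 0]`` and ``Z[i, 1]`` at height
    ``Z[i, 2]`` into new cluster ``C + i``; leaves are 0 ... C-1.  The Ward
    height convention is sqrt(2 * dESS), the square root of twice the
    increase in total within-cluster sum of squares.
    """

    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.ndim != 2 or self.Z.shape[1] != 4:
            raise ValueError("Z must be an (C-1, 4) linkage matrix")
        h = self.heights
        if np.any(np.diff(h) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    @property
    def n_leaves(self) -> int:
        return self.Z.shape[0] + 1


class HierarchicalLabelSet:
    """A nested multi-level partition of the target classes plus sample labels.

    ``maps[i]`` sends each target-class index to its coarse-class index at
    level i+1 (level 1 is the coarsest); ``levels[i]`` are the per-sample
    coarse labels and ``targets`` the per-sample target labels.  Coarse ids
    are contiguous and numbered by each block's smallest target class, so
    hierarchies are directly comparable across runs.
    """

    def __init__(
        self,
        maps: Sequence[np.ndarray],
        targets: np.ndarray,
        class_names: Sequence[str],
        thresholds: Sequence[float] | None = None,
        heights: Sequence[float] | None = None,
    ):
        self.maps = [np.asarray(m, dtype=np.int64) for m in maps]
        self.targets = np.asarray(targets, dtype=np.int64)
        self.class_names = list(class_names)
        self.thresholds = list(thresholds) if thresholds is not None else None
        self.heights = list(heights) if heights is not None else None
        c = len(self.class_names)
        for m in self.maps:
            if len(m) != c:
                raise ValueError("each map must cover every target class")
        self.validate_nesting()

    # -- structure --------------------------------------------------------

    @property
    def n_levels(self) -> int:
        """Total levels K including the target level."""
        return len(self.maps) + 1

    @property
    def level_class_counts(self) -> tuple[int, ...]:
        return tuple(int(m.max()) + 1 for m in self.maps) + (len(self.class_names),)

    def level_partition(self, level: int) -> frozenset[frozenset[int]]:
        """Level as a partition of target-class indices (1-based level, coarsest first)."""
        if level == self.n_levels:
            return frozenset(frozenset([i]) for i in range(len(self.class_names)))
        m = self.maps[level - 1]
        blocks: dict[int, set[int]] = {}
        for cls, coarse in enumerate(m):
            blocks.setdefault(int(coarse), set()).add(cls)
        return frozenset(frozenset(b) for b in blocks.values())

    def validate_nesting(self) -> None:
        """Every finer-level class must map into exactly one coarser-level class."""
        for i, m in enumerate(self.maps):
            if sorted(set(m.tolist())) != list(range(int(m.max()) + 1)):
                raise ValueError(f"level {i + 1} coarse ids are not contiguous from 0")
        for i in range(len(self.maps) - 1):
            coarse, fine = self.maps[i], self.maps[i + 1]
            for f in np.unique(fine):
                parents = np.unique(coarse[fine == f])
                if len(parents) != 1:
                    raise ValueError(
                        f"nesting violated: level-{i + 2} class {f} spans "
                        f"level-{i + 1} classes {parents.tolist()}"
                    )

    # -- labels -----------------------------------------------------------

    @property
    def levels(self) -> list[np.ndarray]:
        """Per-sample labels at every level, coarsest first, target last."""
        return [relabel(self.targets, m) for m in self.maps] + [self.targets]

    def hier_labels(self) -> HierLabels:
        return HierLabels(self.levels, self.level_class_counts)

    def with_targets(self, targets: np.ndarray) -> "HierarchicalLabelSet":
        """Same class hierarchy applied to a different sample set."""
        return HierarchicalLabelSet(
            self.maps, targets, self.class_names, self.thresholds, self.heights
        )

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "class_names": self.class_names,
            "levels": [
                {name: int(m[i]) for i, name in enumerate(self.class_names)}
                for m in self.maps
            ],
            "thresholds": self.thresholds,
            "heights": self.heights,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(
        cls, source: str | Path, targets: np.ndarray | None = None
    ) -> "HierarchicalLabelSet":
        """Load a hierarchy (auto-built or hand-crafted) and validate nesting."""
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        names = payload["class_names"]
        maps = [
            np.array([level[name] for name in names], dtype=np.int64)
            for level in payload["levels"]
        ]
        if targets is None:
            targets = np.arange(len(names))
        return cls(maps, targets, names, payload.get("thresholds"), payload.get("heights"))


# -- pipeline stages -------------------------------------------------------


def split_for_hierarchy(
    ds: WindowedDataset, r_pre: float = 0.5, seed: int = 0
) -> tuple[WindowedDataset, WindowedDataset]:
    """Class-stratified split of the training set into (D_pre, D_adp).

    D_pre (a fraction ``r_pre`` of the samples, rounded) pre-trains the
    plain CNN; D_adp supplies the features the hierarchy is built from.
    Stratification keeps every class present on both sides so that every
    centroid is defined.
    """
    if not 0 < r_pre < 1:
        raise ValueError("r_pre must be in (0, 1)")
    n = len(ds)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    n_pre = int(round(r_pre * n))
    idx = np.arange(n)
    pre_idx, adp_idx = train_test_split(
        idx, train_size=n_pre, random_state=seed, stratify=ds.targets
    )
    d_pre, d_adp = ds.subset(np.sort(pre_idx)), ds.subset(np.sort(adp_idx))
    for name, part in (("D_pre", d_pre), ("D_adp", d_adp)):
        missing = set(range(ds.n_classes)) - set(part.targets.tolist())
        if missing:
            raise ValueError(f"{name} lost classes {sorted(missing)}; dataset too small")
    return d_pre, d_adp


def extract_features(model, windows: np.ndarray, labels: np.ndarray) -> FeatureMatrix:
    """Penultimate-layer activations of a trained CNN for each window."""
    return FeatureMatrix(model.extract_features(windows), labels)


def reduce_pca(fm: FeatureMatrix, d: int = 64, seed: int = 0) -> FeatureMatrix:
    """Project features onto the top-d principal components (centered).

    ``d`` is clamped to what the data supports (min of sample count and
    feature width) with a warning rather than an error, since small
    adaptation sets are routine at test scale.
    """
    feasible = min(fm.F.shape)
    if d > feasible:
        logger.warning("PCA dimension %d clamped to %d (data shape %s)", d, feasible, fm.F.shape)
        d = feasible
    pca = PCA(n_components=d, random_state=seed)
    return FeatureMatrix(pca.fit_transform(fm.F), fm.labels)


def class_centroids(fm: FeatureMatrix, n_classes: int | None = None) -> CentroidSet:
    """Arithmetic mean of feature rows per target class."""
    if n_classes is None:
        n_classes = int(fm.labels.max()) + 1
    centroids = np.empty((n_classes, fm.F.shape[1]))
    for c in range(n_classes):
        rows = fm.F[fm.labels == c]
        if len(rows) == 0:
            raise ValueError(f"class {c} has no feature rows; centroid undefined")
        centroids[c] = rows.mean(axis=0)
    return CentroidSet(centroids)


def ward_dendrogram(cs: CentroidSet) -> Dendrogram:
    """Agglomerative Ward clustering of the class centroids.

    Heights follow the sqrt(2 * dESS) convention: the height of a merge is
    the square root of twice the increase in total within-cluster sum of
    squares it causes (for two singletons this is their Euclidean distance).
    """
    if cs.n_classes < 2:
        raise ValueError("need at least 2 centroids to cluster")
    return Dendrogram(linkage(cs.F_center, method="ward"))


def gap_thresholds(
    dendrogram: Dendrogram, n_levels: int, epsilon: float | None = None
) -> tuple[list[float], list[int]]:
    """Thresholds just above the lower height of the L largest merge-height gaps.

    With sorted merge heights d_0 ... d_{C-2}, the gaps are
    s_i = d_{i+1} - d_i for i = 0 ... C-3.  The L largest gaps are selected
    (ties broken toward larger i, i.e. the coarser cut); each selected index
    j contributes the threshold d_j + epsilon.  Thresholds are returned in
    descending order so the first belongs to Level 1, the coarsest.  Also
    returns the selected gap indices in the same order.
    """
    h = dendrogram.heights
    c = dendrogram.n_leaves
    if n_levels > c - 2:
        raise ValueError(f"cannot cut {n_levels} non-trivial levels from {c} classes")
    gaps = np.diff(h)  # s_i = d_{i+1} - d_i, i = 0 .. C-3
    if epsilon is None:
        span = float(h[-1] - h[0])
        if span <= 0:
            raise ValueError("all merge heights equal; no gap to threshold")
        epsilon = 1e-6 * span
    # ties prefer larger index (the coarser cut)
    order = np.lexsort((np.arange(len(gaps)), gaps))[::-1]
    selected = sorted(order[:n_levels].tolist(), reverse=True)
    min_gap = float(gaps[selected].min()) if selected else 0.0
    if epsilon >= min_gap and min_gap > 0:
        logger.warning(
            "epsilon %g not below the smallest selected gap %g; clamping", epsilon, min_gap
        )
        epsilon = 0.5 * min_gap
    thresholds = [float(h[j] + epsilon) for j in selected]
    return thresholds, selected


def flat_clusters(dendrogram: Dendrogram, threshold: float) -> np.ndarray:
    """Cut the dendrogram: classes joined by merges of height <= threshold share a cluster.

    Cluster ids are renumbered 0 ... n_clusters-1 by each cluster's smallest
    contained target-class index, making partitions comparable across runs.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    raw = fcluster(dendrogram.Z, t=threshold, criterion="distance")
    order: dict[int, int] = {}
    for cluster_id in raw:  # first appearance = smallest class index
        if cluster_id not in order:
            order[cluster_id] = len(order)
    return np.array([order[c] for c in raw], dtype=np.int64)


def relabel(targets: np.ndarray, class_map: np.ndarray | dict) -> np.ndarray:
    """Map per-sample target labels to coarse labels elementwise."""
    targets = np.asarray(targets, dtype=np.int64)
    if isinstance(class_map, dict):
        missing = set(targets.tolist()) - set(class_map)
        if missing:
            raise KeyError(f"labels {sorted(missing)} missing from the class map")
        class_map = np.array([class_map[k] for k in range(max(class_map) + 1)])
    class_map = np.asarray(class_map, dtype=np.int64)
    if targets.size and targets.max() >= len(class_map):
        raise KeyError(f"label {int(targets.max())} missing from the class map")
    return class_map[targets]


def _is_degenerate(m: np.ndarray) -> bool:
    k = int(m.max()) + 1
    return k == 1 or k == len(m)


def build_hierarchy(
    ds: WindowedDataset,
    cfg: HierarchyBuildConfig,
    feature_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> HierarchicalLabelSet:
    """Run the full hierarchy-construction pipeline on a training set.

    When ``feature_fn`` is given (e.g. hand-crafted window statistics, or
    oracle generative parameters in tests), the plain-CNN pre-training is
    bypassed and the function is applied to the adaptation windows instead.

    Degenerate cuts — a threshold that would produce a single cluster, all
    singletons, or a partition identical to an already-selected level — are
    discarded and the next-largest gap is used instead, with a warning.
    """
    stage = "split"
    try:
        d_pre, d_adp = split_for_hierarchy(ds, cfg.r_pre, cfg.seed)

        stage = "features"
        if feature_fn is not None:
            fm = FeatureMatrix(feature_fn(d_adp.windows), d_adp.targets)
        else:
            backbone = cfg.backbone or vgg16_1d_backbone()
            train_cfg = cfg.train_cfg or TrainConfig(epochs=200, seed=cfg.seed)
            std = build_bcnn(
                backbone,
                BranchSpec((), (ds.n_classes,)),
                input_shape=ds.windows.shape[1:],
                seed=cfg.seed,
            )
            labels = HierLabels([d_pre.targets], (ds.n_classes,))
            train(std, d_pre.windows, labels, train_cfg)
            fm = extract_features(std, d_adp.windows, d_adp.targets)

        stage = "pca"
        fm = reduce_pca(fm, cfg.d, cfg.seed)

        stage = "centroids"
        cs = class_centroids(fm, ds.n_classes)

        stage = "ward"
        dendrogram = ward_dendrogram(cs)

        stage = "thresholds"
        h = dendrogram.heights
        gaps = np.diff(h)
        order = np.lexsort((np.arange(len(gaps)), gaps))[::-1].tolist()
        span = float(h[-1] - h[0])
        if span <= 0:
            raise ValueError("all merge heights equal; no usable gap")
        epsilon = cfg.epsilon if cfg.epsilon is not None else 1e-6 * span

        stage = "cuts"
        chosen: list[tuple[int, np.ndarray]] = []
        seen: list[tuple[int, ...]] = []
        for j in order:
            if len(chosen) == cfg.n_coarse_levels:
                break
            eps_j = min(epsilon, 0.5 * gaps[j]) if gaps[j] > 0 else epsilon
            m = flat_clusters(dendrogram, float(h[j] + eps_j))
            key = tuple(m.tolist())
            if _is_degenerate(m) or key in seen:
                logger.warning("gap index %d gives a degenerate/duplicate cut; skipped", j)
                continue
            chosen.append((j, m))
            seen.append(key)
        if len(chosen) < cfg.n_coarse_levels:
            raise ValueError(
                f"only {len(chosen)} usable cuts for {cfg.n_coarse_levels} coarse levels"
            )
        # coarsest first: fewer clusters = higher threshold
        chosen.sort(key=lambda jm: int(jm[1].max()))
        maps = [m for _, m in chosen]
        thresholds = [float(h[j] + min(epsilon, 0.5 * gaps[j])) for j, _ in chosen]

        return HierarchicalLabelSet(
            maps, ds.targets, ds.class_names, thresholds, h.tolist()
        )
    except Exception as exc:
        raise type(exc)(f"hierarchy construction failed at stage '{stage}': {exc}") from exc
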