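"""Subject-wise hold-out evaluation, metrics, and multi-trial aggregation.

One trial = draw a subject-wise train/validation/test split, build the
class hierarchy from the training split only (when requested), train the
model, and evaluate on the held-out subjects.  Trials are repeated with
independent seeds and aggregated by the unweighted mean, following the
benchmark protocol (20 trials; accuracy and macro-averaged F-score at the
target level, plus per-level accuracies for branch models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score

from bcnnhar.hierarchy import HierarchicalLabelSet, HierarchyBuildConfig, build_hierarchy
from bcnnhar.model import BackboneSpec, BranchSpec, BCNN, build_bcnn, tiny_backbone
from bcnnhar.sensor_data import WindowedDataset, subject_holdout_split
from bcnnhar.training import HierLabels, TrainConfig, train

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "TrialProtocol", "evaluate", "run_trial", "run_trials", "compare_models"]


@dataclass
class EvalReport:
    """Target-level accuracy and macro F-score, per-level accuracies, confusion counts.

    Macro F-score is the unweighted mean of per-class F1; a class with no
    true and no predicted positives contributes F1 = 0 (the configurable
    zero-division rule of scikit-learn, fixed here to 0).
    """

    accuracy: float
    macro_f1: float
    per_level_accuracy: list[float]
    confusion: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.macro_f1 <= 1.0):
            raise ValueError("metrics must lie in [0, 1]")
        self.confusion = np.asarray(self.confusion, dtype=np.int64)


@dataclass(frozen=True)
class TrialProtocol:
    """Number of trials, subject split sizes, and per-trial seeds."""

    n_train: int
    n_val: int
    n_test: int
    n_trials: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    @property
    def seeds(self) -> list[int]:
        return [self.base_seed + 1000 * t for t in range(self.n_trials)]


def _batched_scores(model: BCNN, windows: np.ndarray, batch_size: int = 256) -> list[np.ndarray]:
    parts: list[list[np.ndarray]] = [[] for _ in range(model.n_levels)]
    for start in range(0, len(windows), batch_size):
        scores = model.forward(windows[start : start + batch_size], train=False)
        for k, s in enumerate(scores):
            parts[k].append(s)
    return [np.concatenate(p) for p in parts]


def evaluate(model: BCNN, ds: WindowedDataset, hierarchy: HierarchicalLabelSet) -> EvalReport:
    """Evaluate every hierarchy level independently on a windowed dataset."""
    if len(ds) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    hier = hierarchy.with_targets(ds.targets)
    if model.n_levels != hier.n_levels:
        raise ValueError(
            f"model has {model.n_levels} levels but hierarchy has {hier.n_levels}"
        )
    scores = _batched_scores(model, ds.windows)
    level_labels = hier.levels
    per_level_acc = [
        float((s.argmax(axis=1) == y).mean()) for s, y in zip(scores, level_labels)
    ]
    y_pred = scores[-1].argmax(axis=1)
    y_true = ds.targets
    return EvalReport(
        accuracy=per_level_acc[-1],
        macro_f1=float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        per_level_accuracy=per_level_acc,
        confusion=confusion_matrix(y_true, y_pred, labels=range(ds.n_classes)),
    )


def run_trial(
    ds: WindowedDataset,
    protocol: TrialProtocol,
    seed: int,
    *,
    mode: str = "auto",
    backbone: BackboneSpec | None = None,
    branch_positions: Sequence[int] = (1,),
    hierarchy_cfg: HierarchyBuildConfig | None = None,
    manual_hierarchy: HierarchicalLabelSet | None = None,
    train_cfg: TrainConfig | None = None,
    feature_fn=None,
) -> EvalReport:
    """One full trial: split, (build hierarchy,) train, evaluate.

    ``mode`` is ``"std"`` (single-head plain CNN), ``"auto"`` (hierarchy
    constructed from this trial's training subjects only), or ``"manual"``
    (user-supplied hierarchy).  The hierarchy never sees validation or test
    subjects.
    """
    backbone = backbone or tiny_backbone()
    train_cfg = train_cfg or TrainConfig()
    train_ds, val_ds, test_ds = subject_holdout_split(
        ds, protocol.n_train, protocol.n_val, protocol.n_test, seed
    )
    overlap = set(np.unique(train_ds.subjects)) & set(np.unique(test_ds.subjects))
    if overlap:
        raise AssertionError(f"subject leakage between train and test: {overlap}")

    input_shape = ds.windows.shape[1:]
    if mode == "std":
        branch = BranchSpec((), (ds.n_classes,))
        hier = HierarchicalLabelSet([], train_ds.targets, ds.class_names)
        labels = HierLabels([train_ds.targets], (ds.n_classes,))
    elif mode in ("auto", "manual"):
        if mode == "auto":
            cfg = hierarchy_cfg or HierarchyBuildConfig()
            hier = build_hierarchy(train_ds, replace(cfg, seed=seed), feature_fn)
        else:
            if manual_hierarchy is None:
                raise ValueError("manual mode needs a hierarchy")
            hier = manual_hierarchy.with_targets(train_ds.targets)
        branch = BranchSpec(tuple(branch_positions), hier.level_class_counts)
        labels = hier.hier_labels()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    model = build_bcnn(backbone, branch, input_shape, seed=seed)
    train(model, train_ds.windows, labels, replace(train_cfg, seed=seed))
    return evaluate(model, test_ds, hier)


def run_trials(
    ds: WindowedDataset, protocol: TrialProtocol, **trial_kwargs
) -> tuple[dict, list[EvalReport]]:
    """Repeat :func:`run_trial` over the protocol's seeds and aggregate means.

    A failed trial is logged and excluded from the aggregate (with a
    warning); the aggregate dict carries the unweighted mean and standard
    deviation of accuracy and macro F-score over completed trials.
    """
    reports: list[EvalReport] = []
    for seed in protocol.seeds:
        try:
            reports.append(run_trial(ds, protocol, seed, **trial_kwargs))
        except Exception:
            logger.exception("trial with seed %d failed; excluded from aggregate", seed)
    if not reports:
        raise RuntimeError("every trial failed")
    if len(reports) < protocol.n_trials:
        logger.warning("aggregating %d of %d trials", len(reports), protocol.n_trials)
    accs = np.array([r.accuracy for r in reports])
    f1s = np.array([r.macro_f1 for r in reports])
    aggregate = {
        "n_completed": len(reports),
        "accuracy_mean": float(accs.mean()),
        "accuracy_sd": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        "macro_f1_mean": float(f1s.mean()),
        "macro_f1_sd": float(f1s.std(ddof=1)) if len(f1s) > 1 else 0.0,
    }
    return aggregate, reports


def compare_models(
    ds: WindowedDataset, configs: dict[str, dict], protocol: TrialProtocol
) -> pd.DataFrame:
    """Side-by-side aggregate metrics for several model configurations.

    ``configs`` maps a row name to the keyword arguments of
    :func:`run_trial`.  Branch models additionally report mean per-level
    accuracies; the std model's single level is the target level.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations to compare")
    rows = []
    for name, kwargs in configs.items():
        aggregate, reports = run_trials(ds, protocol, **kwargs)
        row = {"model": name, **aggregate}
        if kwargs.get("mode", "auto") != "std":
            n_levels = len(reports[0].per_level_accuracy)
            for k in range(n_levels):
                row[f"level{k + 1}_accuracy_mean"] = float(
                    np.mean([r.per_level_accuracy[k] for r in reports])
                )
        rows.append(row)
    return pd.DataFrame(rows)
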