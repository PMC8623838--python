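"""Reading, trimming, windowing, and subject-wise splitting of accelerometer data.

Recordings are tri-axial accelerometer time series (columns ``time,x,y,z``)
with one activity label and one subject per recording, in the style of
smartphone activity-recognition benchmarks.  Continuous recordings are cut
into fixed-length windows with the sliding-window method; windows inherit
the recording's activity label.  Evaluation splits are subject-wise: all
windows of a subject land in exactly one of train/validation/test, which
prevents identity leakage between splits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SensorRecording",
    "SlidingWindowConfig",
    "WindowedDataset",
    "FormatError",
    "read_recordings",
    "trim_edges",
    "sliding_window",
    "subject_holdout_split",
    "windows_from_recordings",
]


class FormatError(ValueError):
    """Raised when an input file does not match the expected column layout."""


@dataclass(frozen=True)
class SensorRecording:
    """One subject's labeled tri-axial time series at a known sampling rate.

    ``samples`` is an (n, 3) float array of x/y/z acceleration; units are
    whatever the source used (m/s^2 or g) and are never rescaled here.
    """

    subject_id: str
    activity: str
    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got {samples.shape}")
        if samples.shape[0] == 0:
            raise ValueError("recording has no samples")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Window length and stride in samples.

    The default 256/256 (non-overlapping 256-sample windows) is the standard
    smartphone-accelerometer protocol; overlap is supported by setting
    ``stride < window``.
    """

    window: int = 256
    stride: int = 256

    def __post_init__(self) -> None:
        if self.window <= 0 or self.stride <= 0:
            raise ValueError("window and stride must be positive")


@dataclass
class WindowedDataset:
    """Fixed-length windows with per-window target labels and subject ids.

    The unit of training and evaluation.  ``windows`` has shape
    (n, window, 3); ``targets`` holds class indices into ``class_names``;
    ``subjects`` carries the owning subject of each window.
    """

    windows: np.ndarray
    targets: np.ndarray
    subjects: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        if self.windows.ndim != 3 or self.windows.shape[2] != 3:
            raise ValueError(f"windows must be (n, window, 3), got {self.windows.shape}")
        n = self.windows.shape[0]
        if not (len(self.targets) == len(self.subjects) == n):
            raise ValueError("windows, targets, subjects must have equal length")
        if n and (self.targets.min() < 0 or self.targets.max() >= len(self.class_names)):
            raise ValueError("target index out of range of class_names")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.windows[idx], self.targets[idx], self.subjects[idx], list(self.class_names)
        )

    def save(self, path: str | Path) -> None:
        """Write arrays as .npz plus a JSON sidecar with the class names."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            windows=self.windows,
            targets=self.targets,
            subjects=self.subjects.astype(str),
        )
        sidecar = {"class_names": self.class_names}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WindowedDataset":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"), allow_pickle=False)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            arrays["windows"], arrays["targets"], arrays["subjects"], sidecar["class_names"]
        )


def read_recordings(
    path: str | Path,
    metadata: str | Path | Mapping[str, tuple[str, str]],
    *,
    columns: Sequence[str] = ("time", "x", "y", "z"),
    rate_hz: float = 100.0,
    delimiter: str = ",",
) -> list[SensorRecording]:
    """Read a directory (or single file) of delimited recordings.

    ``metadata`` maps each file name to ``(subject, activity)``; it may be a
    mapping or the path of a CSV with columns ``filename,subject,activity``.
    Files missing any of the expected columns raise :class:`FormatError`
    naming the file; empty files are skipped with a warning.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]

    if not isinstance(metadata, Mapping):
        meta_df = pd.read_csv(metadata, dtype=str)
        metadata = {
            row["filename"]: (row["subject"], row["activity"]) for _, row in meta_df.iterrows()
        }

    recordings: list[SensorRecording] = []
    for f in files:
        if f.name not in metadata:
            if path.is_dir():
                logger.warning("skipping %s: not listed in the metadata", f.name)
                continue
            raise FormatError(f"{f.name}: no subject/activity metadata supplied")
        try:
            df = pd.read_csv(f, sep=delimiter)
        except pd.errors.EmptyDataError:
            logger.warning("skipping empty file %s", f)
            continue
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise FormatError(f"{f.name}: missing columns {missing} (found {list(df.columns)})")
        if len(df) == 0:
            logger.warning("skipping file with no rows %s", f)
            continue
        subject, activity = metadata[f.name]
        samples = df[list(columns[1:4])].to_numpy(dtype=np.float64)
        recordings.append(SensorRecording(subject, activity, samples, rate_hz))
    return recordings


def trim_edges(rec: SensorRecording, seconds: float) -> SensorRecording:
    """Drop ``round(seconds * rate_hz)`` samples from each end of a recording.

    Benchmark protocols trim a few seconds from each measurement file to
    discard the pocket-in/pocket-out transients (5 s for HASC-style files,
    3 s for WISDM-style segments).
    """
    if seconds < 0:
        raise ValueError("trim duration must be non-negative")
    n_trim = int(round(seconds * rec.rate_hz))
    if n_trim == 0:
        return rec
    if 2 * n_trim >= len(rec):
        raise ValueError(
            f"trimming {n_trim} samples from each end empties a recording of length {len(rec)}"
        )
    return SensorRecording(
        rec.subject_id, rec.activity, rec.samples[n_trim:-n_trim], rec.rate_hz
    )


def sliding_window(rec: SensorRecording, cfg: SlidingWindowConfig) -> np.ndarray:
    """Cut a recording into fixed-length windows; returns (n_windows, window, 3).

    Produces ``floor((len - window) / stride) + 1`` windows when the
    recording is long enough, else an empty array.  No zero-padding.
    """
    n = len(rec)
    if n < cfg.window:
        return np.empty((0, cfg.window, 3), dtype=np.float32)
    starts = range(0, n - cfg.window + 1, cfg.stride)
    return np.stack([rec.samples[s : s + cfg.window] for s in starts]).astype(np.float32)


def windows_from_recordings(
    recordings: Iterable[SensorRecording],
    cfg: SlidingWindowConfig | None = None,
    *,
    class_names: Sequence[str] | None = None,
    standardize: bool = False,
) -> WindowedDataset:
    """Window every recording and assemble a :class:`WindowedDataset`.

    Each window inherits its recording's activity label.  ``class_names``
    fixes the label order; by default labels are sorted lexicographically.
    ``standardize`` applies per-channel zero-mean/unit-variance scaling
    over the whole dataset; it is off by default because models are meant
    to see raw acceleration values (gravity included).
    """
    cfg = cfg or SlidingWindowConfig()
    recordings = list(recordings)
    if class_names is None:
        class_names = sorted({r.activity for r in recordings})
    index = {name: i for i, name in enumerate(class_names)}

    all_windows, targets, subjects = [], [], []
    for rec in recordings:
        w = sliding_window(rec, cfg)
        if len(w) == 0:
            logger.warning(
                "recording %s/%s shorter than one window; skipped", rec.subject_id, rec.activity
            )
            continue
        all_windows.append(w)
        targets.extend([index[rec.activity]] * len(w))
        subjects.extend([rec.subject_id] * len(w))
    if not all_windows:
        raise ValueError("no recording produced a single window")
    windows = np.concatenate(all_windows)
    if standardize:
        mean = windows.mean(axis=(0, 1), keepdims=True)
        sd = windows.std(axis=(0, 1), keepdims=True)
        windows = (windows - mean) / np.where(sd > 0, sd, 1.0)
    return WindowedDataset(
        windows, np.asarray(targets), np.asarray(subjects), list(class_names)
    )


def subject_holdout_split(
    ds: WindowedDataset, n_train: int, n_val: int, n_test: int, seed: int
) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Assign whole subjects to train/validation/test by a seeded uniform draw.

    Subjects are sorted before the draw so the assignment depends only on
    the subject set and the seed.  No subject straddles two splits.
    """
    subjects = sorted(np.unique(ds.subjects).tolist())
    needed = n_train + n_val + n_test
    if needed > len(subjects):
        raise ValueError(
            f"split needs {needed} subjects but the dataset has only {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(subjects), size=needed, replace=False)
    picked = [subjects[i] for i in drawn]
    groups = (
        set(picked[:n_train]),
        set(picked[n_train : n_train + n_val]),
        set(picked[n_train + n_val :]),
    )
    parts = []
    for group in groups:
        mask = np.isin(ds.subjects, list(group))
        parts.append(ds.subset(np.flatnonzero(mask)))
    return tuple(parts)
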