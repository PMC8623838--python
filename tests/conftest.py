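import numpy as np
import pytest

from bcnnhar.sensor_data import SensorRecording, WindowedDataset
from bcnnhar.synthetic import (
    SyntheticDatasetConfig,
    default_benchmark_specs,
    generate_dataset,
)

#: ground-truth grouping of the six-class benchmark (still | walk-like | vigorous)
TRUE_GROUPS = frozenset([frozenset([0]), frozenset([1, 2, 3]), frozenset([4, 5])])


@pytest.fixture(scope="session")
def benchmark_cfg() -> SyntheticDatasetConfig:
    return SyntheticDatasetConfig(
        tuple(default_benchmark_specs()),
        n_subjects=4,
        windows_per_subject_per_class=20,
        seed=0,
    )


@pytest.fixture(scope="session")
def benchmark_ds(benchmark_cfg) -> WindowedDataset:
    return generate_dataset(benchmark_cfg)


def make_oracle_features(ds: WindowedDataset, cfg: SyntheticDatasetConfig):
    """Feature extractor returning each window's true generative parameter vector."""
    params = np.stack([s.param_vector for s in cfg.specs])
    lookup = {ds.windows[i].tobytes(): int(ds.targets[i]) for i in range(len(ds))}

    def fn(windows):
        return params[[lookup[w.tobytes()] for w in windows]]

    return fn


@pytest.fixture
def recording() -> SensorRecording:
    rng = np.random.default_rng(42)
    return SensorRecording("subjA", "walk", rng.normal(size=(2000, 3)), rate_hz=100.0)
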