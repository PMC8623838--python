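"""Class hierarchy-adaptive branch CNNs for sensor-based human activity recognition.

A branch CNN (B-CNN) attaches auxiliary classifier heads at intermediate
depths of a 1D convolutional backbone; each head predicts one level of a
class hierarchy and the model is trained with a weighted sum of per-level
softmax cross-entropy losses.  The class hierarchy itself is constructed
automatically from training data: features from a pre-trained plain CNN are
reduced with PCA, per-class centroids are clustered with Ward linkage, and
the largest gaps between dendrogram merge heights select the thresholds that
cut the dendrogram into coarse levels.
"""

from bcnnhar.sensor_data import (
    SensorRecording,
    SlidingWindowConfig,
    WindowedDataset,
    read_recordings,
    sliding_window,
    subject_holdout_split,
    trim_edges,
)
from bcnnhar.synthetic import (
    SyntheticClassSpec,
    SyntheticDatasetConfig,
    default_benchmark_specs,
    generate_dataset,
)
from bcnnhar.model import (
    BackboneSpec,
    BranchSpec,
    ConvBlockSpec,
    BCNN,
    build_bcnn,
    tiny_backbone,
    vgg16_1d_backbone,
)
from bcnnhar.training import (
    LossSpec,
    TrainConfig,
    amplitude_invert,
    axis_swap,
    bcnn_loss,
    one_hot,
    ricap_1d,
    train,
)
from bcnnhar.hierarchy import (
    HierarchicalLabelSet,
    HierarchyBuildConfig,
    build_hierarchy,
    class_centroids,
    flat_clusters,
    gap_thresholds,
    reduce_pca,
    relabel,
    split_for_hierarchy,
    ward_dendrogram,
)
from bcnnhar.analysis import (
    count_two_level_hierarchies,
    enumerate_two_level_hierarchies,
    pair_merge_percentage,
    accuracy_distribution_summary,
)
from bcnnhar.experiment import EvalReport, TrialProtocol, compare_models, evaluate, run_trials

__version__ = "0.1.0"

__all__ = [
    "SensorRecording", "SlidingWindowConfig", "WindowedDataset",
    "read_recordings", "sliding_window", "subject_holdout_split", "trim_edges",
    "SyntheticClassSpec", "SyntheticDatasetConfig",
    "default_benchmark_specs", "generate_dataset",
    "BackboneSpec", "BranchSpec", "ConvBlockSpec", "BCNN",
    "build_bcnn", "tiny_backbone", "vgg16_1d_backbone",
    "LossSpec", "TrainConfig", "amplitude_invert", "axis_swap",
    "bcnn_loss", "one_hot", "ricap_1d", "train",
    "HierarchicalLabelSet", "HierarchyBuildConfig", "build_hierarchy",
    "class_centroids", "flat_clusters", "gap_thresholds", "reduce_pca",
    "relabel", "split_for_hierarchy", "ward_dendrogram",
    "count_two_level_hierarchies", "enumerate_two_level_hierarchies",
    "pair_merge_percentage", "accuracy_distribution_summary",
    "EvalReport", "TrialProtocol", "compare_models", "evaluate", "run_trials",
]
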