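"""Multi-level loss, augmentations, and the training loop."""

import numpy as np
import pytest
from scipy.special import logsumexp

from bcnnhar.model import BranchSpec, build_bcnn, tiny_backbone
from bcnnhar.sensor_data import WindowedDataset
from bcnnhar.training import (
    HierLabels,
    LossSpec,
    TrainConfig,
    amplitude_invert,
    axis_swap,
    bcnn_loss,
    bcnn_loss_grad,
    one_hot,
    ricap_1d,
    train,
)


class TestLoss:
    def test_one_hot(self):
        np.testing.assert_array_equal(one_hot(2, 4), [0, 0, 1, 0])
        np.testing.assert_array_equal(one_hot(0, 1), [1])
        with pytest.raises(IndexError):
            one_hot(4, 4)

    def test_uniform_scores_closed_form(self):
        scores = [np.zeros((1, 2)), np.zeros((1, 6))]
        labels = HierLabels([np.array([0]), np.array([3])], (2, 6))
        spec = LossSpec((0.5, 0.5), (2, 6))
        expected = 0.5 * np.log(2) + 0.5 * np.log(6)
        assert abs(bcnn_loss(scores, labels, spec) - expected) < 1e-9

    def test_single_level_equals_reference_cross_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.normal(size=(8, 5))
            t = rng.integers(0, 5, size=8)
            ours = bcnn_loss([y], HierLabels([t], (5,)), LossSpec((1.0,), (5,)))
            ref = float(np.mean(logsumexp(y, axis=1) - y[np.arange(8), t]))
            assert abs(ours - ref) < 1e-9

    def test_equal_weights_sum_to_one(self):
        spec = LossSpec.equal((2, 4, 6))
        assert spec.weights == (1 / 3, 1 / 3, 1 / 3)
        with pytest.raises(ValueError, match="sum to 1"):
            LossSpec((0.5, 0.6), (2, 6))

    def test_decomposes_into_weighted_levels(self):
        rng = np.random.default_rng(1)
        scores = [rng.normal(size=(6, 2)), rng.normal(size=(6, 4))]
        labels = HierLabels([rng.integers(0, 2, 6), rng.integers(0, 4, 6)], (2, 4))
        spec = LossSpec((0.3, 0.7), (2, 4))
        per_level = [
            bcnn_loss([s], HierLabels([l], (c,)), LossSpec((1.0,), (c,)))
            for s, l, c in zip(scores, labels.levels, (2, 4))
        ]
        total = bcnn_loss(scores, labels, spec)
        assert abs(total - (0.3 * per_level[0] + 0.7 * per_level[1])) < 1e-9

    def test_loss_vanishes_with_growing_margin(self):
        losses = []
        for margin in (1.0, 5.0, 20.0):
            y = np.array([[margin, 0.0, 0.0]])
            losses.append(
                bcnn_loss([y], HierLabels([np.array([0])], (3,)), LossSpec((1.0,), (3,)))
            )
        assert losses[0] > losses[1] > losses[2] and losses[2] < 1e-6

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        scores = [rng.normal(size=(4, 3)), rng.normal(size=(4, 5))]
        labels = HierLabels([rng.integers(0, 3, 4), rng.integers(0, 5, 4)], (3, 5))
        spec = LossSpec((0.4, 0.6), (3, 5))
        grads = bcnn_loss_grad(scores, labels, spec)
        eps = 1e-6
        for k in range(2):
            for i in range(4):
                for c in range(scores[k].shape[1]):
                    up = [s.copy() for s in scores]
                    dn = [s.copy() for s in scores]
                    up[k][i, c] += eps
                    dn[k][i, c] -= eps
                    fd = (bcnn_loss(up, labels, spec) - bcnn_loss(dn, labels, spec)) / (2 * eps)
                    assert abs(fd - grads[k][i, c]) < 1e-4


class TestAugmentations:
    def _batch(self, n=8, t=32, seed=0):
        rng = np.random.default_rng(seed)
        batch = rng.normal(size=(n, t, 3)).astype(np.float32)
        labels = HierLabels([rng.integers(0, 2, n), rng.integers(0, 4, n)], (2, 4))
        return batch, labels

    def test_ricap_preserves_shape_and_mixes_labels(self):
        batch, labels = self._batch()
        mixed, soft = ricap_1d(batch, labels, np.random.default_rng(0))
        assert mixed.shape == batch.shape
        for level, c in zip(soft.levels, (2, 4)):
            assert level.shape == (8, c)
            np.testing.assert_allclose(level.sum(axis=1), 1.0, atol=1e-9)
            assert (level >= 0).all()

    def test_ricap_label_weights_match_segment_lengths(self):
        batch, labels = self._batch(n=4, t=100)

        class FixedRng:
            def beta(self, a, b):
                return 0.25

            def permutation(self, n):
                return np.roll(np.arange(n), 1)

        mixed, soft = ricap_1d(batch, labels, FixedRng())
        hard = labels.to_soft()
        perm = np.roll(np.arange(4), 1)
        for level, mixed_level in zip(hard, soft.levels):
            np.testing.assert_allclose(mixed_level, 0.25 * level + 0.75 * level[perm])
        np.testing.assert_array_equal(mixed[:, :25], batch[:, :25])
        np.testing.assert_array_equal(mixed[:, 25:], batch[perm, 25:100])

    def test_ricap_beta_mean(self):
        """Mean Beta(0.5, 0.5) boundary fraction is 1/2."""
        rng = np.random.default_rng(3)
        draws = [rng.beta(0.5, 0.5) for _ in range(10_000)]
        assert abs(np.mean(draws) - 0.5) < 0.02

    def test_ricap_batch_of_one_unchanged(self):
        batch, labels = self._batch(n=1)
        out, out_labels = ricap_1d(batch, labels, np.random.default_rng(0))
        np.testing.assert_array_equal(out, batch)
        assert out_labels is labels

    def test_axis_swap_permutes_channels(self):
        batch, _ = self._batch(n=50)
        out = axis_swap(batch, np.random.default_rng(1))
        assert out.shape == batch.shape
        for i in range(50):
            got = {tuple(np.round(out[i, :, c], 5)) for c in range(3)}
            want = {tuple(np.round(batch[i, :, c], 5)) for c in range(3)}
            assert got == want  # channel multiset invariant

    def test_amplitude_invert_flips_whole_channels(self):
        batch, _ = self._batch(n=50)
        out = amplitude_invert(batch, np.random.default_rng(2))
        ratio = out / batch
        assert np.isin(np.round(ratio, 6), [-1.0, 1.0]).all()
        # each channel has a single sign
        assert (np.abs(ratio.mean(axis=1)) > 0.999).all()
        np.testing.assert_allclose(out.var(axis=1), batch.var(axis=1), rtol=1e-5)


class TestTrain:
    def test_separable_problem_learned(self):
        """Two well-separated classes reach >= 0.95 training accuracy in 30 epochs."""
        rng = np.random.default_rng(0)
        n = 40
        t = np.arange(64) / 50.0
        lo = np.sin(2 * np.pi * 1.0 * t)[None, :, None] + rng.normal(0, 0.2, (n, 64, 3))
        hi = 3 * np.sin(2 * np.pi * 8.0 * t)[None, :, None] + rng.normal(0, 0.2, (n, 64, 3))
        x = np.concatenate([lo, hi]).astype(np.float32)
        y = np.repeat([0, 1], n)
        model = build_bcnn(tiny_backbone((4, 8)), BranchSpec((), (2,)), (64, 3), seed=0)
        cfg = TrainConfig(epochs=30, batch_size=16, seed=0,
                          ricap=False, axis_swap=False, amplitude_invert=False)
        history = train(model, x, HierLabels([y], (2,)), cfg)
        assert len(history) == 30
        acc = (model.forward(x)[0].argmax(axis=1) == y).mean()
        assert acc >= 0.95

    def test_training_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 32, 3)).astype(np.float32)
        y = rng.integers(0, 3, 30)
        histories = []
        for _ in range(2):
            model = build_bcnn(tiny_backbone((3, 4)), BranchSpec((), (3,)), (32, 3), seed=5)
            histories.append(
                train(model, x, HierLabels([y], (3,)), TrainConfig(epochs=3, seed=5))
            )
        np.testing.assert_array_equal(histories[0]["loss"], histories[1]["loss"])

    def test_multi_level_training_reduces_both_losses(self, benchmark_ds):
        sub = benchmark_ds.subset(np.arange(0, len(benchmark_ds), 4))
        coarse = np.array([0, 1, 1, 1, 2, 2])[sub.targets]
        labels = HierLabels([coarse, sub.targets], (3, 6))
        model = build_bcnn(tiny_backbone((4, 8)), BranchSpec((1,), (3, 6)), (256, 3), seed=2)
        history = train(model, sub.windows, labels, TrainConfig(epochs=8, seed=2))
        assert history["level1_ce"].iloc[-1] < history["level1_ce"].iloc[0]
        assert history["level2_ce"].iloc[-1] < history["level2_ce"].iloc[0]

    def test_empty_dataset_rejected(self):
        model = build_bcnn(tiny_backbone((3, 4)), BranchSpec((), (2,)), (32, 3))
        with pytest.raises(ValueError, match="empty"):
            train(model, np.zeros((0, 32, 3)), HierLabels([np.zeros(0, int)], (2,)),
                  TrainConfig(epochs=1))
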