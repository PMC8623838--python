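# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `bcnnhar` at the level of detail a user extending the
package needs.

## Problem setting

Sensor-based human activity recognition from tri-axial accelerometer
streams: recordings are trimmed at the edges (pocket-in/pocket-out
transients), segmented into fixed windows of 256 samples with stride 256
(overlap supported but off by default), and labeled with the recording's
single activity.  Evaluation is subject-wise hold-out: all windows of a
subject fall into exactly one of train/validation/test, drawn uniformly
without replacement from the lexicographically sorted subject list under a
seed, so a split is a pure function of (subject set, seed).  The benchmark
protocol draws 20 such trials and averages accuracy and macro F-score.  No
amplitude normalization or filtering is applied anywhere; raw values reach
the model (an optional per-channel standardization flag exists but
defaults off).

## Branch CNN

The backbone is a stack of Conv Blocks: `n_conv` length-preserving 1D
convolutions (kernel 3, ReLU, no batch normalization) followed by max
pooling with factor 2; odd sequence lengths floor-divide at pooling.  The
default full-scale backbone is the VGG16 layout — (2,2,3,3,3) convolutions
with (64,128,256,512,512) filters — with a width multiplier (0.5 = "S",
2 = "W" variants).  A `tiny_backbone` (one convolution per block, 8/16
filters by default) is the CPU-scale configuration used throughout the
tests.

Each hierarchy level gets one head: global average pooling over time, then
a single fully connected layer straight to the C_k scores.  Coarse heads
attach after configurable block positions (1-based, strictly increasing);
the target head sits after the last block.  K = 1 with no positions is the
plain "std" model, and its parameter count is exactly backbone + one head.
Levels are predicted independently — the model never projects the fine
prediction onto the coarse one or vice versa, so the two heads can
disagree and both answers are reported as-is.

Weight initialization is He fan-in for convolutions, seeded.  Heads are
**zero-initialized**: every model then starts from the uniform predictor
(initial loss Σ w_k log C_k), which matters at short training budgets —
with feature magnitudes dominated by the constant gravity offset (~9.8), a
randomly initialized head starts at a loss several times log C and can
spend most of a 30-epoch run undoing its own initialization.

The loss is the weighted sum of per-level softmax cross-entropies with
weights that must sum to one (equal per level by default).  Soft (mixed)
targets use the same formula.  Gradients are hand-derived
(w_k·(softmax − t)/batch at each head, accumulated through the shared
trunk at branch points) and are verified against central finite
differences in the test suite at tolerance 1e-4.

## Augmentations

Applied per batch, in order, each with probability 1:

- **RICAP (1D)**: segment boundaries are drawn once per batch from
  Beta(β, β), β = 0.5; each output window concatenates time segments from
  independently permuted copies of the batch, and labels at *every*
  hierarchy level become mixtures of the sources' one-hot labels weighted
  by segment length.  Two segments by default (the 2D original's four
  patches have one natural concatenation axis in 1D); a 4-segment variant
  refines each half with a second Beta draw.  A batch of one is returned
  unchanged with a warning.
- **Axis swap**: a uniformly random permutation of the x/y/z channels per
  window (identity included) — sensor orientation in a pocket is
  arbitrary.
- **Amplitude inversion**: each channel's sign flipped independently with
  probability ½.

Optimization is Adam at learning rate 0.001 with default moments and no
schedule; 300 epochs for branch models and 200 for the plain model at full
scale (tests use 20–30).  Batch size is not protocol-fixed; the default is
64.  Augmentation is applied both to branch training and to the plain
model used inside hierarchy construction (a config flag disables it).

## Automatic hierarchy construction

Given a training set covering all C classes:

1. **Split** into D_pre / D_adp with ratio r_pre = 0.5, stratified by
   class so both halves contain every class (|D_pre| = round(r_pre·N)).
2. **Pre-train** the plain CNN on D_pre.
3. **Features**: penultimate post-GAP activations of D_adp windows.  A
   pluggable `feature_fn` bypasses pre-training (used in tests with
   hand-crafted window statistics or oracle generative parameters).
4. **PCA** to d = 64 dimensions, fitted on the D_adp features only; d is
   clamped with a warning when the data cannot support it.
5. **Centroids**: per-class arithmetic means.
6. **Ward dendrogram** over the centroids.  Heights follow the
   √(2·ΔESS) convention — the height of a merge is the square root of
   twice the increase in total within-cluster sum of squares, so two
   singletons merge at their Euclidean distance.  Heights are verified
   against a brute-force greedy ΔESS oracle in the tests (1e-8).
7. **Gap thresholds**: with sorted heights d_0 … d_{C−2}, gaps are
   s_i = d_{i+1} − d_i for i ≤ C−3; the L largest gaps are selected and
   each contributes a threshold d_j + ε.  Ties prefer the larger index
   (the coarser cut).  ε defaults to 1e-6 of the height range, clamped to
   half the smallest selected gap so a threshold never jumps the gap it
   was selected for.
8. **Cuts**: classes joined by merges of height ≤ t share a coarse class;
   cluster ids are renumbered by smallest contained target class so
   hierarchies compare across runs.  A cut that is degenerate (single
   cluster, all singletons — possible only through ties) or duplicates an
   already-selected level is discarded for the next-largest gap, with a
   warning.

Restricting gap indices to i ≤ C−3 already guarantees every cut has
between 2 and C−1 clusters.  Because all levels cut one dendrogram, the
levels are nested by construction; nesting is still validated explicitly
on every hierarchy (and on user-supplied JSON hierarchies, which share the
same container and checks).  The branch model is always trained from fresh
initial weights — nothing is transferred from the pre-trained plain model.

## Hierarchy space enumeration

A two-coarse-level hierarchy is an ordered pair (P1, P2) of partitions of
the C target classes with P2 a strict merging of the classes (≥ 1 merge,
≥ 2 blocks) and P1 a strict further merging of P2 (≥ 2 blocks).
Partitions are encoded as restricted-growth strings, which makes equality
insensitive to block naming and gives a deterministic enumeration order.
The count has the closed form Σ_{k2=3}^{C−1} S(C,k2) · Σ_{k1=2}^{k2−1}
S(k2,k1) (Stirling numbers of the second kind), asserted equal to the
exhaustive enumeration for C ≤ 8 in the tests: 18 at C = 4, 205 at C = 5,
1865 at C = 6, 1,542,699 at C = 9.  Counts of roughly this magnitude are
sometimes quoted for slightly different inclusion rules of the trivial
levels; the rule here is fixed by the C = 4 case and documented as above.
Co-merge statistics (`pair_merge_percentage`) report, for a collection of
hierarchies, the fraction in which each class pair shares a block at a
given level; `accuracy_distribution_summary` bins grid-search accuracies
and extracts the top/bottom ceil(q·n) hierarchies for that analysis.

## Synthetic benchmark

The generator produces what hierarchy construction needs to be testable
offline: windows with a known latent group structure.  Each class is a
phase-randomized sinusoid plus a 0.3-amplitude second harmonic at a
class-specific frequency and amplitude, on a constant gravity offset
(0, 0, 9.8), with white noise, at 50 Hz over 256-sample windows.  Subject
individuality is multiplicative lognormal jitter (sd 0.03) on frequency
and amplitude, drawn once per (subject, class).

The default six-class set mirrors a basic-activity benchmark: `still`
(amplitude 0), a walk-like group at 1.9/2.0/2.1 Hz with amplitude 2, and a
vigorous group at 3.55/3.60 Hz with amplitude 4 and differing noise
levels.  Two properties drove these choices:

- **Within-group similarity is real, not nominal.**  Same-group classes
  share amplitude and noise scale and differ by cadence offsets at or
  below the subject-jitter scale, so they overlap across subjects the way
  stair-up/stair-down do in practice.  This matters because the features
  used for clustering come from a *discriminatively trained* CNN: if
  same-group classes are easy to separate, training actively pulls them
  apart in feature space and the latent grouping is no longer the
  dominant geometry.
- **Between-group contrast dominates the learned feature scale.**
  Post-ReLU GAP features scale with signal amplitude, so frequency
  differences are amplified in proportion to amplitude.  The amplitude
  tiers 0/2/4 and the moderate vigorous-group cadence keep the smallest
  between-group feature distance well above the largest within-group one.
  The analogous contract in parameter space — smallest between-group
  (frequency, amplitude) distance ≥ 3× the largest within-group distance
  — is asserted at configuration time.

What the generator does **not** emulate: biomechanical waveform shape,
transitions between activities, orientation drift, heteroscedastic or
colored sensor noise, and class imbalance.  Passing the recovery tests
therefore shows the pipeline recovers a latent similarity structure that
is expressed in the data; it does not show that real benchmark classes
possess such structure, nor predict real-data accuracy.

## Problem sizes used in tests

Tests and the acceptance checks run the full pipeline at deliberately
small scale, chosen as the smallest sizes at which the studied effects are
stable: the tiny two-block backbone (three blocks when two branch
positions are needed), 4–6 subjects with 20 windows per subject and class,
20–30 training epochs, and 1–3 hold-out trials per configuration.  The
hierarchy-recovery check builds the hierarchy from CNN features on 20
seeded datasets and requires the generative grouping at Level 2 in at
least 18; the model comparison averages 10 seeded std-vs-branch trials at
2 training subjects.  Full-scale defaults (VGG16, 300/200 epochs, 20
trials) remain the configured defaults for real use.

## Numerical and design notes

- All computation is float32 forward/backward with float64 loss
  reductions; everything is seeded through `numpy.random.default_rng` and
  bit-reproducible on one machine.
- Max pooling drops a trailing remainder shorter than the pool factor;
  global average pooling makes heads length-agnostic, so 256-sample
  windows survive five pools (256 → 8).
- Macro F-score uses the zero-division rule F1 = 0 for classes with no
  true and no predicted positives (configurable in scikit-learn terms,
  fixed to 0 here).
- The validation split is reserved for monitoring; no early stopping or
  model selection uses it.
- Trimming is applied per recording file before windowing.
- Branch positions are configuration, not searched: the package exposes
  them per backbone but does not auto-tune.

## Known limitations

- The NumPy network is CPU-bound and single-threaded beyond BLAS; the
  full VGG16 at benchmark scale is hours of compute, so real-data
  replications should expect long runs or a port of the model module to a
  GPU framework (the module boundary — specs in, score lists out — was
  drawn to make that a drop-in).
- Hierarchy quality inherits the known sensitivity to the pre-trained
  feature space: a softmax-trained plain CNN can place a static class
  nearer an ambulatory group than their semantics suggest, and the
  resulting hierarchy reflects the feature geometry, not human intuition.
- The enumeration module is exact but only practical to C ≈ 9–10;
  beyond that the counts themselves are the argument for the automatic
  method.
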