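# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Pipeline overview

A high-density surface EMG (HD-sEMG) recording is a `channels × frames`
matrix tied to a 2D electrode grid.  The pipeline is:

1. **Conditioning** (raw bipolar recordings): zero-lag fourth-order
   Butterworth band-pass, 20–400 Hz.  Forward–backward filtering
   (`scipy.signal.filtfilt`, reflective padding of `3 × order` samples)
   cancels the phase response so burst onsets are not delayed.
   Pre-segmented data already normalized to [−1, 1] skips this step.
2. **Activity segmentation**: full-wave rectification and a zero-lag 4 Hz
   low-pass give a per-channel intensity envelope.  On non-overlapping
   windows of 150 samples (73.2 ms at 2048 Hz) the channel-mean intensities
   are summed; the threshold is the mean of the window sums; the longest
   contiguous strictly-supra-threshold run is the activity segment.  The
   segment length is therefore always a multiple of the window length.
3. **Image/cube formation**: signals are mapped linearly to [0, 1]
   (per-recording extrema for raw data; the fixed range [−1, 1] for
   pre-normalized data) and each frame is arranged by electrode geometry
   into an `h × w` image; sliding windows of `l` consecutive images form
   `l × h × w × 1` cubes.  Training may use an overlapping stride as
   augmentation; test-time extraction is non-overlapping.
4. **Classification**: a 3D CNN over cubes, or its 2D ablation over single
   frames.  Architecture (both variants): conv 32/64/64 kernels (3×3×3 or
   3×3), stride 1, zero padding 0×1×1 (spatial 1×1) on conv2/conv3,
   temporal-only pooling `s×1×1` after conv2 and conv3 (absent in 2D),
   dense 512/128 with dropout 0.5, batch norm before every non-linearity,
   G-way softmax.
5. **Decision fusion**: majority voting over the per-cube predictions of a
   voting window (`nc` consecutive cubes, `nc · t_cube` ms, kept ≤ 300 ms
   for real-time use); the within-window fraction of correct per-cube
   predictions is reported alongside.

## Numerical and design choices

Open points in the architecture family and their resolutions:

- **Temporal pooling semantics**: ceiling division with a truncated
  boundary window, so a temporal extent of 1 survives pooling.  Floor
  semantics would annihilate the `l = 10` configuration (trace
  10 → 8 → 6 → 3 → 1).
- **Pooling operator**: not specified by the family; both max and average
  are implemented (`pool_op` on the builder).  Max is the default — the
  common choice in spatiotemporal networks — because it retains the
  temporal position of salient activation within the pooled window, which
  is exactly the cue that distinguishes motion directions; average
  pooling smooths the stochastic carrier better but smears that position
  information.  The choice is recorded in every run report.
- **Pooling placement**: after conv2 and after conv3 (the padding+pooling
  description attaches to the second and third convolutional layers).
- **Loss**: the two-class cross-entropy form generalizes to categorical
  cross-entropy over the G-way softmax, which is what training minimizes;
  the binary form is kept as a utility for G = 2.
- **Learning-rate schedule**: "no improvement after 10 iterations" is
  interpreted with an iteration = one epoch (configurable to per-batch);
  the rate is halved when the best loss has not improved for 10
  consecutive epochs, then the counter resets.
- **Argmax ties** resolve to the smallest class index; **majority-vote
  ties** resolve to the most recent occurrence among the tied labels
  (favoring the newest evidence in an online setting; configurable to
  smallest-label).
- **Voting windows** are non-overlapping and never span trial boundaries;
  trailing cubes not filling a window are dropped.
- **Weight initialization**: variance-scaled uniform
  (±√(6/fan_in)) from the run seed.  Training is deterministic given the
  seed: initialization, shuffling, and dropout masks share one generator.
- **Segmentation ties** (window sum exactly equal to the threshold) count
  as inactive (strict `>`); a constant envelope therefore yields "no
  activity detected".  Only the longest burst is kept — one gesture per
  trial implies a single dominant burst.
- **Half/half split**: alternating trial indices per gesture (even → train,
  odd → test); deterministic.
- **Unit conversion**: window lengths in ms convert to frames as
  `floor(ms · fs / 1000)` (150 ms at 2048 Hz → 307 frames).

## Parameter-count conventions

Published totals of "weights to be learnt" depend on bookkeeping that is
rarely stated.  `count_parameters` therefore takes a convention tag;
`examples/02_parameter_counts.py` prints all four for the reference
configurations:

- `none` — conv/dense weights and biases only;
- `bn-channel` — plus 2 trainable parameters (γ, β) per normalized channel
  (the standard modern convention);
- `bn-channel-full` — plus the 2 moving statistics per channel;
- `bn-activation` — batch normalization placed before **every** weighted
  layer including the network input, with γ/β per input activation
  (2 trainable parameters per element of each weighted layer's input
  tensor), trainable parameters counted.

The reference totals for this architecture family (2.90 and 3.77 ×10⁶ for
the 2D variants; 3.08 ×10⁶ for 3D at cube length 10 on the 8×16 grid;
7.88 ×10⁶ for 3D at 20 ms on the 7×24 grid at 2048 Hz) are reproduced
exactly — to their printed precision — under `bn-activation`, which is
therefore the documented convention for table reproduction and the default
in the experiment reports.  Per-activation batch norm is also an
instantiable mode of the trainable model (`bn_mode="activation"`), so the
analytic count can be checked against an enumeration of a live model's
tensors for every tag.  For actually training the desk-scale models the
package uses the conventional per-channel batch norm.

## The synthetic benchmark

The generator emulates the statistical structure the pipeline relies on,
not muscle physiology:

- **Gesture**: an isotropic Gaussian activation bump (σ = 1.2 px) on the
  grid; its value at each electrode amplitude-modulates that channel's
  carrier.
- **Carrier**: per-channel independent Gaussian white noise band-passed to
  20–400 Hz, unit variance (the band the conditioning chain assumes).
- **Trial**: 3 s rest–activity–rest; activity occupies the middle half
  (fractions 0.25–0.75) with raised-cosine ramps over 10% of the active
  duration, smooth enough for the 4 Hz envelope filter to track.
- **Noise**: white, with standard deviation set 10 dB (default) below the
  plateau signal RMS.  With amplitude 0 the trial is exactly zero and
  segmentation must report no activity.
- **Static vs dynamic**: static gestures (isometric holds) keep the bump
  centroid fixed at one of G well-separated centers.  Dynamic gestures
  move it; the dynamics-only benchmark uses **pairs sharing one center,
  circling it in opposite directions** (radius 2 px, period 0.25 s), so
  the two members of a pair have *identical single-frame statistics* and
  only the temporal evolution within a cube separates them.  A linear
  centroid path cannot achieve this on a small grid over a multi-second
  trial, which is why the generator supports circular orbits in addition
  to linear drift.
- **Reproducibility**: per-trial RNG streams are spawned from
  (master seed, gesture, trial), so datasets are identical across runs and
  independent of generation order.

What passing tests on this substrate show: that every stage — filtering,
thresholding segmentation, image/cube bookkeeping, the convolution
arithmetic, training dynamics, voting — behaves as specified, and that the
spatiotemporal classifier can exploit information a per-frame classifier
provably cannot see.  What they do not show: performance on real HD-sEMG,
which has motor-unit action-potential waveforms, electrode artifacts,
inter-subject variability and nonstationarity that the generator does not
model.

### Difficulty of the dynamic task

The per-cube motion cue is deliberately subtle (the centroid moves ≈1 px
per 20-frame cube under multiplicative carrier noise).  A matched-filter
ideal observer that knows the center, radius and period and maximizes over
orbital phase reaches ≈95% direction accuracy at `l = 20`, so the
information is present; a desk-scale CNN trained for a few minutes
recovers only part of it.  The 3D-vs-2D comparison is therefore
directional — the 3D network must beat the per-frame ablation, which is
capped near the pair-identification rate times ½ — rather than a claim of
near-oracle accuracy.

## Desk-scale experiment sizes

The protocol runner and the end-to-end tests use reduced widths
(conv 8/16/16, dense 64/32 — the same family, smaller budget), G = 4
gestures, 8 trials per gesture, cube length 10 (static) or 20 (dynamic)
frames, training stride 20, 30 epochs of SGD (momentum 0.9, batch 32,
lr 0.1 with plateau halving).  These sizes were chosen so a full run
completes in minutes on one CPU while leaving the architecture and
pipeline logic identical to the full-scale configuration; the full-width
networks are exercised analytically (shape propagation and parameter
counting) rather than trained.

## Known limitations

- The numpy training loop is single-threaded and unsuited to full-scale
  training (32/64/64 kernels on hundreds of thousands of cubes); the
  package's trainable runs are desk-scale by design.
- The generator's carrier is spatially independent across channels; real
  HD-sEMG has strong spatial correlation and propagating motor-unit
  potentials.
- Only the longest activity burst per trial is segmented; multi-burst
  trials (rare in single-gesture protocols) would need the interval table
  extended.
- The MATLAB container adapter is read-only and assumes the benchmark's
  frames × channels layout.
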