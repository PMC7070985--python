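# hdsemg3d

Gesture recognition from high-density surface electromyography (HD-sEMG)
with spatiotemporal convolutional networks, end to end: signal
conditioning and muscle-activity segmentation, instantaneous sEMG images
and sliding-window cubes, a 3D CNN classifier with its 2D (per-frame)
ablation, majority-voted decisions, and a synthetic grid-signal generator
so the whole pipeline runs and is testable with no external data.

## The problem and the method

An HD-sEMG device records muscle electrical activity on a dense 2D
electrode grid (e.g. 8 × 16 monopolar channels at 1000 Hz, or 7 × 24
usable bipolar channels at 2048 Hz).  Each time frame, arranged by
electrode geometry, is an *instantaneous sEMG image*; a run of `l`
consecutive frames stacked along time is a *cube* `l × h × w × 1`.  A 2D
CNN classifies a single image and sees only the spatial pattern of
activation; a 3D CNN convolves `d × k × k` kernels over the cube,

```
v_ij(x, y, z) = f( b_ij + Σ_m Σ_p Σ_q Σ_r  w_ijm(p, q, r) · v_(i−1)m(x+p, y+q, z+r) )
```

and captures how the activation pattern *moves* — the information that
separates gestures whose single-frame appearance is identical.

The classifier family is fixed: three convolutional layers of 32/64/64
kernels (3×3×3 spatiotemporal, stride 1×1×1, zero padding 0×1×1 on the
second and third), temporal-only pooling `s×1×1` after conv2 and conv3,
fully connected layers of 512 and 128 units, dropout 0.5, batch
normalization before every non-linearity, and a G-way softmax.  Training
is SGD on the cross-entropy loss with initial rate 0.1, halved after 10
iterations without improvement.  At decision time, consecutive per-cube
predictions within a voting window (kept under the 300 ms real-time
bound) are fused by simple majority voting.

Raw bipolar recordings are conditioned with a zero-lag fourth-order
Butterworth band-pass (20–400 Hz); activity is located by thresholding
the intensity envelope (rectification + zero-lag 4 Hz low-pass) on
non-overlapping 150-sample windows, keeping the longest supra-threshold
run.  Signals are mapped linearly to [0, 1] before image formation.

## Worked example

```
$ python examples/01_simulate_and_segment.py
trial: 128 channels x 3000 frames at 1000 Hz
ground-truth activity: frames [750, 2250)
detected segment:      frames [750, 2250)  (10 windows of 150)
```

A synthetic 3 s trial (Gaussian activation bump amplitude-modulating a
20–400 Hz carrier, 10 dB above baseline noise) is conditioned and
segmented; the detected burst matches the ground-truth interval exactly
here, and within one 150-frame window in general.

```
$ python examples/02_parameter_counts.py
configuration                                             none      bn-channel bn-channel-full   bn-activation
2D, 8x16 grid, G=8                                   2,875,464       2,877,064       2,878,664       2,903,880
2D, 7x24 grid, G=27                                  3,729,883       3,731,483       3,733,083       3,766,699
3D, cube 10x8x16, pool 2, G=8                        2,986,632       2,988,232       2,989,832       3,076,488
3D, cube 40x7x24 (20 ms @2048 Hz), pool 4, G=27      7,445,531       7,447,131       7,448,731       7,882,651
```

Each network configuration's trainable weights are counted analytically
from the declarative spec under four bookkeeping conventions (see
`docs/methods.md`); under `bn-activation` the totals are 2.90, 3.77,
3.08 and 7.88 ×10⁶.

```
$ python examples/03_train_and_vote.py
593 training cubes of shape (10, 8, 16, 1) from 8 trials
final training loss: 0.141
voted accuracy over 150 ms windows: 100.0%
mean within-window fraction correct: 95.9%
confusion matrix (rows = true gesture, cols = predicted):
[[19  0  0  0]
 [ 0 20  0  0]
 [ 0  0 20  0]
 [ 0  0  0 20]]
```

A reduced-width 3D network (conv 8/16/16, dense 64/32 — same family,
smaller budget) trained for 20 epochs on the static 4-gesture synthetic
benchmark classifies every 150 ms voting window of the held-out trials
correctly; the per-cube (pre-voting) rate is 95.9%, showing what the
voting stage contributes.

There is also a thin CLI (`emg3d simulate / preprocess / segment / cubes /
train / evaluate / sweep / run / table1`) wrapping the same library calls
stage by stage, so each pipeline step is independently runnable on its
file formats.

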