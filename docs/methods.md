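# Methods

## Problem and approach

Quantitative analysis of vocal-fold oscillation from laryngeal high-speed
videoendoscopy needs two ingredients per frame: the segmented glottal area
(the opening between the vocal folds) and the glottal midline, the axis about
which left/right oscillation symmetry is measured. The midline is anchored by
two anatomical landmarks — the anterior point (AP) and the posterior point
(PP) at the two ends of the glottal opening — and, for a well-recorded video,
is constant across frames.

`glottikit` treats the problem as a multitask dense-prediction task. A single
convolutional encoder–decoder network predicts, in one forward pass:

- a segmentation probability map of the glottal area, and
- two *localization maps*, one per landmark, in the style of keypoint/pose
  estimation: the target for each landmark is an image-sized binary map
  containing a filled disk of radius *r* centered on the landmark.

Predicted landmark coordinates are decoded from the maps (thresholded
intensity-weighted centroid), the midline is the line through the decoded
AP/PP pair, and a moving median over frames suppresses frame-to-frame jitter
of the decoded trajectory.

## Architectures

All models are 4-level U-Nets with a per-level filter schedule
`base_filters * 2^level` (8–64 base filters), 3×3 convolutions, 2×2 max
pooling, 2×2 transposed-convolution upsampling, batch or instance
normalization, and sigmoid output heads. The six 2-D variants differ in where
the two tasks separate along the decoding path, from sharing everything but
the final 1×1 convolutions (`v2a`) to two complete decoders that both
originate in the latent bottleneck Ψ and both receive encoder skip
connections (`v2e`, the recommended configuration). `v1_regression` is the
baseline design that regresses the four point coordinates directly from Ψ
via global average pooling and a dense layer; it is included for comparison
because map-based localization is the central methodological improvement
over it.

Three temporal extensions consume multi-frame clips:

- `channels`: the frame window enters as input channels of the 2-D network;
  the prediction is for the center frame, and video inference slides the
  window with edge replication.
- `conv3d`: all convolutions become 3-D (time × height × width); pooling and
  upsampling remain spatial, so the network emits one prediction per frame.
- `convlstm`: each double convolution is replaced by a single ConvLSTM2D
  layer; the last decoder step uses two 3-D convolutions. Per-frame outputs.

The `conv3d` and `convlstm` builders extend the dual-decoder (`v2e`)
topology only, since that is the configuration the temporal modes are meant
to improve on; requesting them with another variant is a configuration
error. Whether the second decoder of `v2e` should receive encoder skip
connections or only Ψ is a genuinely open design point; we include the skips
(both decoders are full U-Net decoders) because it is the stronger and more
symmetric reading.

The network layer is implemented on a compact reverse-mode automatic
differentiation engine over numpy arrays (`glottikit.nn`): convolution is a
primitive (im2col forward, col2im backward, verified against central finite
differences), 3-D convolution is composed from per-offset 2-D convolutions,
and everything else (norms, ConvLSTM gates, losses) is composed from
elementwise/reduction primitives whose gradients come for free. This keeps
the package dependency-light and fully deterministic under a seed.

## Targets, losses, training

- **Localization targets.** Binary disks (inclusive boundary,
  `(c-x)^2 + (r-y)^2 <= radius^2`, evaluated against the float sub-pixel
  center). A Gaussian-bump option exists behind a flag, but the default is
  binary because training uses plain MSE on the maps and decoding normalizes
  by the map maximum. Reference radius: 15 px at 512×256, scaled
  proportionally with image height (7.5 px at 256×128). For very small desk-
  scale images the proportional rule under-samples the disk, so the CLI
  floors the radius at 3 px; the synthetic study protocol below uses 3 px at
  64×32 for the same reason.
- **Losses.** Soft Dice (smoothing ε = 1, so frames with a fully closed
  glottis — empty masks — remain finite) for segmentation; pixelwise MSE
  for the localization maps; weighted sum with default weights (1, 1).
- **Optimizer and schedules.** Adam throughout. Learning-rate policies:
  `constant`; `exp_decay` (γ = 0.95); `scheduler1`, step decay halving every
  10 epochs; and the default `scheduler2`, linear warmup over 3 epochs to
  `lr0` followed by 0.9^k decay. The two numbered schedulers are this
  package's presets. Default `lr0 = 3e-3`, chosen for the small desk-scale
  models this package trains by default; large-scale configurations
  typically want rates one to two orders of magnitude lower.
- **Validation.** 10 % of videos (never frames of a video split across
  sides), evaluated each epoch for combined loss, IoU and MAPE; the retained
  checkpoint is the epoch with the best validation MAPE.
- **Augmentation.** Horizontal flip, rotation (±30°), Gaussian blur, random
  gamma, additive Gaussian noise; pool expansion factor 10 by default.
  Geometric ops resample image and mask but transform the points
  analytically (flip: `x -> W-1-x`; rotation about the image center matching
  the resampler's screen-space angle) and rebuild the target maps from the
  transformed points, so keypoint labels are exact by construction. A
  rotation that would push a landmark out of the image is rejected and
  redrawn. The rotation range and photometric magnitudes are package
  choices; only the set of operations is prescribed.

## Decoding and temporal filtering

Each predicted map is thresholded at half its maximum and the intensity-
weighted centroid of the supra-threshold pixels is returned; this inverts
the disk encoding exactly (sub-0.5 px error across radii 5–20) and degrades
gracefully on plateaued or multi-modal maps (the documented behavior for a
perfectly ambiguous two-peak map is the global centroid). Row-major argmax
is available as an option. An all-zero channel raises an error naming the
channel rather than fabricating a point.

Trajectories of decoded points are smoothed per coordinate with a moving
median of window *w* (useful range 6–18 frames; ~12 frames corresponds to
about one oscillation cycle at typical recording rates). The series is
padded with `ceil((w-1)/2)` leading replicates of the first value and
`floor((w-1)/2)` trailing replicates of the last, so length is preserved;
even windows average the two central order statistics. The window counts
frames, not pixels.

## Evaluation metrics

- **MAPE** per image over the four coordinate scalars
  (`ap_x, ap_y, pp_x, pp_y`): `(100/4) * Σ |y_i − y_true,i| / |y_true,i|`,
  averaged over images for a dataset score, summarized as
  median/Q1/Q3/min/max with linearly interpolated quantiles. Coordinates
  are shifted to 1-based pixels before division (exposed flag), because a
  0-based true coordinate of 0 would make the relative error undefined; the
  per-coordinate relative-error reading of the percentage error is a stated
  convention of this package.
- **IoU** on binary masks, with both-empty = 1.0 (an empty prediction for a
  closed glottis is correct).
- **Jitter**: per video and landmark, the population standard deviation
  over frames of the Euclidean distance between the predicted point and the
  constant true position.

## Synthetic data

The generator renders seedable clips that emulate the statistical structure
of annotated endoscopy snippets without any photorealism: a lens-shaped
(vesica, two circular arcs) glottal opening between fixed AP/PP tips, dark
against a brighter background, whose half-width follows
`max_half_width * |sin(π t / cycle_frames)|` (full closure at phase 0), plus
clipped additive Gaussian pixel noise. Per-video parameters (midline angle
±15° from vertical, glottal length 0.56–0.87 of the short frame side, peak
half-opening ≈ a tenth of it, noise σ 0.01–0.05, background 0.55–0.75,
cycle 10–14 frames) are drawn from ranges that scale with the frame so the
same relative anatomy appears at any resolution; each video gets an
independent child seed. Defaults produce 30-frame clips at 64×32.

What this emulates: a constant per-video midline, periodic opening/closing
including fully closed frames, sub-pixel landmark positions, moderate sensor
noise, inter-video anatomical variability. What it does not: specular
highlights, mucus, motion blur, camera shake, pathological left/right
asymmetry, or realistic laryngeal texture. Passing tests on this data
demonstrate that the pipeline is implemented correctly and can recover
landmarks and areas it was trained to see; they are not evidence of clinical
performance on real endoscopy.

## Desk-scale study protocol and known limitations

Tests and the reproduction script run a deliberately small end-to-end study:
variant `v2e`, 8 base filters, instance normalization, 64×32 inputs, disk
radius 3 px, 10 training clips × 20 frames (200 frames), `scheduler2` with
`lr0 = 3e-3`, batch 8, no augmentation; held-out evaluation on 5 fresh
clips. Training takes a few minutes on one CPU core. Typical results:
held-out median MAPE in the low single digits of percent and mean IoU
≈ 0.9, with validation MAPE falling severalfold from epoch 1.

Limitations worth knowing:

- At this scale the keypoint task shows visible seed-to-seed spread (held-
  out median MAPE roughly 4–16 % across seeds): with ~200 low-resolution
  frames the anterior-point decoder can settle in a diffuse local optimum
  before the schedule decays. Larger corpora, higher resolution, and
  augmentation stabilize it; the segmentation task is robust across seeds.
- Batch normalization uses batch statistics during training and running
  averages at inference; instance normalization (the default) uses instance
  statistics in both regimes.
- The numpy engine is single-threaded apart from BLAS matmuls and is built
  for clarity and desk-scale experiments, not for training at
  publication scale.
- The `channels` temporal mode predicts the center frame of its window; the
  choice of reference frame is a package decision.
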