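# Methods

## The switching controller

The controller treats the activation function of a network as a
schedulable hyperparameter.  A run consists of `AFCS_loop` training
segments.  Before the first segment every candidate in the ordered list
`list_AF` is *probed*: from a common reference checkpoint the candidate is
activated and trained for `probe_epochs` epochs (default 1), and its final
validation loss recorded.  Candidates are ranked ascending by that loss,
with ties broken by list order; a non-finite probe ranks last and is
flagged.  The best candidate becomes the active activation, and the worst
is removed from the list.  The initial removal is unconditional; later
removals happen only while the list is longer than `min_AF_count`, and the
just-selected best is never removed even if it is also ranked worst (which
can only happen when a single candidate remains).

Each segment trains under a patience rule.  In the default
`consecutive_increases` mode a counter increments on every epoch whose
validation loss strictly exceeds the previous epoch's and resets on any
non-increase; the segment ends when the counter reaches `p0` (first
segment) or `p1` (later segments).  A NaN loss counts as a degradation and
can never become the best.  The alternative `no_best_improvement` mode
counts epochs without a new best loss, as in classic early stopping; it is
exposed because the two rules differ on plateaus (a flat loss never
triggers the default mode but does trigger the alternative), and some
training regimes plateau rather than degrade.

On a trigger the run restores the best-validation-loss checkpoint seen so
far (`rollback_mode="best"`, the default; `"last"` keeps the current
weights), re-probes the surviving candidates *from that checkpoint*, and
switches.  Rolling back means the degraded epochs are discarded and every
candidate is compared on equal footing from the best state.  The switch is
recorded at the epoch of the restored checkpoint — the epoch training
continues from — so schedule epochs are non-decreasing and the first
record is always epoch 1.  At segment start the previous-loss reference is
seeded with the restored best loss; a segment that degrades immediately
therefore costs exactly `p1` epochs, which is what makes the measured
post-best epochs of a fully-triggered run equal the cost model

    extra_epochs = p0 + (AFCS_loop - 1) * p1.

Probe epochs are excluded from this model (its three worked evaluations
account only for patience epochs); the run log reports probe costs
separately.  A safety bound `epoch_cap` on total segment epochs guards
against runs whose loss never degrades; hitting it returns a truncated
result with the best checkpoint restored and `truncated=True`.

Patience values below 2 are accepted with a warning (the cost model's own
examples use `p1 = 1`), although the nominal domain of all three loop
parameters starts at 2.

## Patience calibration

The defaults `p0 = 3`, `p1 = 2` are derived, not guessed.  The package
bundles reference validation-loss traces from fixed-activation trainings
of two architectures (VGG16 and DenseNet121, three repeats each, seven
candidate activations) in two phases: from-scratch segments, and segments
continued from each repeat's best activation.  For every trace the
*consecutive degradation number* is measured: the longest run of
consecutive epochs that fail to improve the best-so-far validation loss,
i.e. the maximum value a Keras-style early-stopping wait counter reaches.
This statistic reproduces every one of the 126 published count cells
bundled alongside the traces (36 first-segment, 90 continued-segment).
A simpler statistic — the total number of strict epoch-over-epoch
increases — is also provided (`count_loss_increases`) for trace
diagnostics, but it does not reproduce the published cells and is not used
for calibration.

Counts are averaged per experiment (mean over that row's present cells,
rounded to two decimals), the per-experiment means are averaged into an
overall mean (again two decimals), and the patience is
`round-half-up(overall) + 1`: tolerate the typical number of consecutive
degradations and act on the next.  The calibrating model is the one with
the *highest* overall mean (DenseNet121: 2.39 and 1.38, hence 3 and 2;
VGG16's means are 0.56 and 0.02), so the patience is conservative across
architectures.

## Preprocessing

Plant-image masking keeps pixels whose color lies inside the inclusive
per-channel window (27, 45, 45)–(100, 255, 255) and zeroes the rest,
leaving the plant on a black background.  The window is applied to the raw
RGB channels by default, exactly as the bounds are written.  Because the
same numbers read naturally as a green *hue* window in HSV (hue 27–100 on
the 0–179 scale, saturation/value at least 45), an HSV mode is provided;
the two modes select different pixel sets (a pure green (0, 200, 0) fails
the RGB window but passes the HSV one) and neither is silently preferred.
Masking is idempotent and never amplifies a channel.  Resizing is bilinear
to 224 x 224 without preserving aspect ratio.  Splits (80/20 or 70/15/15)
are stratified by class with a fixed seed — class imbalance makes
unstratified splits unstable at these sizes — and are exhaustive, disjoint
and reproducible.

## Metrics

All classification metrics derive from the K x K confusion matrix (rows =
true class).  Per-class precision divides by the column sum (0 for a class
never predicted), recall by the row sum; F1 is their harmonic mean.
Averaging is weighted by class support by default, with macro available;
the averages are computed in exact rational arithmetic on the integer
counts, so the identity accuracy = weighted recall holds exactly.
Cross-entropy is the mean negative log-probability of the true class in
nats, with predictions clipped to `[1e-7, 1]` before the log.

## Synthetic data

`make_blob_dataset` generates K-class image sets: class k's prototype is a
Gaussian blob at a distinct position on a circle, in a distinct hue, of
peak amplitude `signal_strength` above a flat background; images add
i.i.d. Gaussian pixel noise of standard deviation `noise_sd` and clip to
[0, 255].  At `noise_sd = 0` a nearest-prototype classifier is perfect; at
`signal_strength = 0` it is at chance.  The defaults (4 classes, 30
images/class, 32 px, signal 40, noise 80) put the task in a low
signal-to-noise regime chosen so that a small CNN both learns an
above-chance signal and genuinely overfits — its validation loss degrades
for several consecutive epochs — because that degradation is the very
phenomenon the controller responds to; at high signal-to-noise the
validation loss of this small model decreases monotonically and a
patience-based controller would simply never fire.  What passing tests on
these sets demonstrate is the correctness of the control flow, the swap
machinery and the training plumbing on a learnable problem; they say
nothing about accuracy on real photographs, which differ in every
interesting way (texture, pose, illumination, class structure).

`make_green_plant_image` places an exact, seeded fraction of pixels inside
the mask window (uniform within the bounds) and the rest strictly outside
(in HSV mode both sides are rejection-sampled so the guarantee survives
the round trip through 8-bit RGB), returning the ground-truth mask.

`TinyCNN` is a two-block numpy CNN (3x3 same-padding convolutions with 8
and 16 filters, 2x2 mean pooling, linear softmax head; about 5,500
parameters) trained with minibatch Adamax at its standard defaults (step
size 1e-3, betas 0.9/0.999, epsilon 1e-7), batch size 16, on categorical
cross-entropy, inputs scaled to [0, 1], He-initialized from the seed.
Both convolution nonlinearities are registered swappable sites; the
softmax head is not.  Snapshots capture weights, optimizer state, RNG
state, epoch counter and the active activation, making restore an exact
round-trip and whole runs bit-reproducible.  The scripted trainer replays
per-activation loss columns with per-activation position counters that are
part of the snapshot; an optional plateau mode repeats a column's last
value once exhausted, and otherwise running past a column is an explicit
scenario-coverage error.

## Numerical choices and edge cases

* Activation closed forms: ELU uses alpha = 1; SELU the canonical
  constants lambda = 1.05070098..., alpha = 1.67326324...; GELU the
  exact-erf form rather than the tanh approximation (the reference
  definition; the difference is below test tolerances anyway); Mish is
  computed as `x * tanh(softplus(x))` with a stable log1p-based softplus.
  Derivatives are analytic and verified against central differences.
* Probe ties break by candidate order (stable sort), making rankings
  deterministic.
* Degradation comparisons are strict (`>`); equal consecutive losses do
  not count as increases in the default patience mode.
* Two-decimal rounding happens per experiment row *before* the overall
  calibration mean, matching how the reference tables print their
  averages; integer rounding for patience is half-up.
* The seed argument of `rank_activations` reseeds the trainer's data-order
  RNG only if the trainer exposes `reseed`; otherwise checkpoint restore
  (which includes RNG state) already gives every candidate the same data
  order.

## Problem sizes

Desk-scale defaults keep everything on one CPU: the end-to-end controller
run (tiny CNN, 4 classes x 30 images, 32 px, 6 candidates, 5 cycles)
trains roughly 120 epochs plus ~25 probe epochs in well under a minute,
and the full test suite runs in under a minute.  Larger models and real
datasets slot in through `TrainerPort` without touching the controller.

## Known limitations

* The bundled calibration traces cover two architectures on one benchmark
  at desk scale; recalibrating patience for a new model/dataset pair means
  collecting fresh traces with `afcs calibrate --traces`.
* `TinyCNN` is a correctness vehicle, not a performance baseline: no
  augmentation, no regularization, mean (not max) pooling, and a single
  dense head.
* The controller assumes validation loss is a meaningful per-epoch signal;
  with very small validation sets the patience counter reacts to noise,
  which is partly why rollback-to-best is the default.
* HSV-mode masking depends on the float HSV conversion; bounds are applied
  after scaling hue to 0-179, and pixels exactly on a converted boundary
  can differ from integer-HSV implementations by one unit.
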