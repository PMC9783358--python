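# Methods

This note documents the models, conventions and design choices behind
`actimage`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, what the synthetic data does and does not emulate, and
where the known limitations are.

## Data model and normalization

A recording is a channels × samples matrix of raw inertial values with one
activity label per sample and a declared sampling rate. Channel order is
fixed (ax, ay, az, wx, wy, wz; the accelerometer-only mode uses the first
three). Units are metadata only: every downstream stage operates on
min–max-normalized values x̂ = (x − x_min)/(x_max − x_min) ∈ [0, 1].

Normalization scope is per channel over the recording by default, with an
option to supply fixed sensor ranges (e.g. ±8 g, ±500 °/s) instead. The
per-recording default matches the idea of scaling "raw IMU data" without
assuming calibrated cross-recording ranges; the fixed-range option exists
because per-recording statistics make windows from different recordings
incomparable in absolute terms. A degenerate channel (x_max = x_min, e.g. a
gyroscope axis during quiet standing) maps to all zeros rather than NaN.

Segmentation uses 0-based half-open windows [start, start + L) with starts
at multiples of step = round(L · (1 − overlap)); a trailing partial window
is discarded. Defaults: 2.5 s windows, 50 % overlap (250 samples at 100 Hz;
the 50 Hz/2.56 s and 20 Hz/2.50 s modes are the same code with L = 128 or
50). Windows spanning more than one label are dropped and counted in an
optional report — segmentation is intended to run within labeled activity
bouts, where mixed windows cannot occur.

## Activity images

Conversion is sample-for-pixel: intensity = round(255 · x̂) with
round-half-up (the convention is arbitrary but must be fixed; half-up keeps
0.5 → 128). Channel rows are stacked vertically in the canonical order, so
the raw image of a 6-channel window is 6 × 250. Resizing to the classifier
input (224 × 224) happens in two stages: each channel row is replicated
k = round(W/H) times so every channel becomes a contiguous horizontal band
of equal height, then the banded matrix is interpolated (bilinear by
default; nearest available) and clamped to [0, 255]. Two-stage resizing
keeps the channel-band geometry explicit instead of letting a single
interpolation smear 6 rows across 224. Constant inputs stay exactly
constant; conversion is monotone per sample; distinct normalized values
≥ 1/255 apart stay distinct before resizing.

Images persist as 8-bit grayscale PNG (lossless) plus a JSON manifest
carrying label, provenance and source window; a dataset directory is valid
only if manifest and files agree both ways.

## Augmentation (the enhanced state)

Each image yields exactly 8 deterministic variants: reflection about the
horizontal and vertical axes; rotation about the center at the lower and
upper angular limit (±30°); scaling about the center at 0.9 and 1.1; and
translation at (−10, −10) and (+10, +10) px. The "two limits per technique"
reading for reflection means its two axes — the only interpretation
consistent with 8 variants and a 9× enhanced dataset. Translation applies
both axes jointly by default; an axis-separate mode (4 translation
variants, 10 total) exists but is non-default precisely because it breaks
the 9× arithmetic. Rotation/scale/translation use bilinear interpolation
with exposed pixels filled by a constant (0 = black, the intensity of
sensor silence after normalization); outputs are clamped and re-quantized.
Augmenting a dataset concatenates originals with all variants, so every
class grows by exactly 9× and class proportions are invariant.

## Synthetic cohorts

The generator emulates lower-back (L5) inertial recordings of four
activities at 100 Hz (6 channels; a 20 Hz 3-channel mode mirrors
smartphone-accelerometer datasets). Each activity is a sum of up to three
harmonics of a class-specific fundamental plus white Gaussian noise and a
constant gravity-like baseline:

- fundamentals: walking 1.8 Hz, stair ascent 1.4 Hz, stair descent 1.6 Hz,
  standing 0 Hz (static, zero amplitudes). Distinct fundamentals make
  noise-free cohorts separable by construction, verified independently by a
  spectral nearest-peak classifier;
- gyroscope channels get relatively larger amplitudes in the stair classes
  (rotational activities express themselves in angular velocity);
- noise_sd default 1.0 in units of the walking fundamental amplitude: the
  non-periodic residual of impaired gait is of the same order as the
  periodic component, which is the regime limited clinical cohorts live in;
- each recording receives a random sensor tilt — a small 3-D rotation
  (angle ~ N(0, 10°), random axis) applied to the accelerometer and
  gyroscope triads — emulating device placement/orientation variability
  between recordings and subjects. This matters: per-channel min–max
  normalization erases plain gain or offset perturbations, so without tilt
  the generated windows of a class differ only by phase and noise, and
  *position* augmentation would have nothing real to compensate. Tilt is
  the generator's model of the variation that reflection/rotation/scale/
  translation of images is meant to absorb.

Cohort generation produces exactly the requested number of windows per
class (presets mirror the three limited clinical cohorts: healthy
50/50/49/50, Parkinson's 81/64/60/75, stroke 49/18/31/75). Each window
comes from a fresh single-activity recording whose random stream derives
from (seed, class index, window index), so cohorts are reproducible and
independent of generation order.

What the generator does **not** emulate: biomechanically realistic gait
(asymmetry, stride-time variability, transients), tremor or hemiparesis,
activity transitions, and subject identity (every window is an independent
"subject"). Consequently, passing pipeline tests demonstrates mechanical
and statistical correctness of the pipeline — not clinical-grade
recognition accuracy on real patients.

## Classifier

`tinycnn` is a deliberately small network shaped by the image geometry:

1. block-mean downsampling 224 × 224 → 28 × 28 (the images are band-wise
   redundant, having been upsampled from 6 × 250);
2. a fixed bank of 8 one-dimensional Gabor-style filters — cosine and sine
   phases at stripe periods 4, 6, 8 and 12 px, Hann-windowed, zero-mean,
   unit-norm — convolved along the time axis of each row, then ReLU.
   Stripe period in an activity image is the step-cycle period, so a small
   band-pass bank spans the discriminative temporal structure;
3. global average pooling over time, yielding one feature per (row,
   filter). Pooling out the time axis removes the arbitrary gait phase of
   a window — the dominant nuisance variable;
4. a whitening layer: regularized ZCA, (Σ + εI)^(−1/2) with
   ε = 0.01 × mean eigenvalue, fitted on the training features and frozen.
   The feature geometry is strongly anisotropic (static-vs-dynamic
   directions dwarf the gait-class directions); whitening equalizes them so
   the short standard training schedule converges along the fine
   discriminative directions too. The ε floor keeps near-null directions
   from being amplified into noise;
5. a dense softmax head, one output per class.

Mirroring the fine-tuning paradigm (frozen feature extractor, retrained
head), only the head trains: mini-batch SGD with momentum 0.9 on the
cross-entropy loss under the standard protocol — 5 epochs, learning rate
0.001, batch size 32, stratified 80/20 split (per class, floor(0.8 n) to
training, remainder to test). Head initialization, batch order and the
split all derive from one seed, and the implementation is pure numpy, so
fits are bit-reproducible on one device.

The pretrained backbones used at scale (ResNet18/50, MobileNet-v2,
GoogleNet) are registered names: their weights are external artifacts, so
requesting one raises a clear error stating the input contract (224 × 224,
grayscale replicated to three channels, replaced K-way head) rather than
silently substituting.

Split granularity is per image. With 50 %-overlapping windows, adjacent
windows share half their samples, so a per-image split leaks information
between train and test; this is inherent to the protocol being mirrored
and is deliberately not silently "fixed". The synthetic cohorts sidestep
it (windows are generated independently), and the controlled augmentation
comparison (below) additionally keeps augmented copies of test images out
of training.

## The two run states and the augmentation comparison

The pipeline's `initial` state converts windows to images and trains on
them; the `enhanced` state augments all images 9× *before* the split,
faithfully mirroring the protocol it reproduces (its test set then contains
augmented images, with the leakage noted above). The controlled comparison
`compare_augmentation_effect` instead splits the originals per seed,
augments only the training side, and evaluates both states on the identical
held-out originals — the clean measurement of the augmentation effect. The
directional claim asserted by the test suite is the modest, qualitative
one: enhanced ≥ initial held-out accuracy in at least 8 of 10 seeded
repetitions on a noisy imbalanced cohort.

## Numerical conventions

- round-half-up for intensity quantization and for display rounding
  (accuracy to 1 decimal, other metrics to 3);
- metric conventions: accuracy = 100 × trace/total on the full K×K matrix;
  sensitivity, specificity, F1, MCC per class one-vs-rest, macro-averaged
  (unweighted); a class with a zero denominator contributes 0 for that
  metric. Published benchmark metric rows reproduce from their printed
  confusion matrices only under unweighted macro averaging, which locks
  the convention;
- degenerate channels normalize to 0; empty confusion matrices refuse to
  produce metrics rather than emitting NaN;
- all seeds are plain integers; derived streams use `numpy.random.default_rng`
  with structured seed sequences (seed, class, index).

## Known limitations

- The scratch CNN is not a substitute for large pretrained backbones in
  accuracy terms on real data; it exists to make the pipeline testable and
  reproducible end to end on one CPU.
- Synthetic realism is intentionally minimal (see above); absolute
  accuracies on synthetic cohorts do not transfer to clinical data.
- The enhanced-state protocol inherits the augment-before-split leakage of
  the design it mirrors; use the controlled comparison for methodological
  conclusions.
- Min–max normalization is sensitive to outlier samples (a single spike
  compresses the rest of the channel into a narrow intensity band); no
  robust-scaling option is currently provided.
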