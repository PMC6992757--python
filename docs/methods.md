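# Methods

## Problem and representation

`vtloc` localizes 21 named anatomical landmarks of the vocal-tract area
(tongue tip, velum tip, lip vermillion junctions, epiglottis, teeth points,
…; see `vtloc.schema`) on 2-D midsagittal grayscale images. The package
was designed around the acquisition geometry of static midsagittal MRI
with a 256 × 256 mm field of view at 1 mm/px, but every component takes
the image size and resolution as parameters.

Landmark coordinates are represented as *heat-maps in channels*: channel
*l* of an *N*<sub>r</sub> × *N*<sub>c</sub> × *L* stack carries an
untruncated Gaussian hat

&nbsp;&nbsp;&nbsp;&nbsp;G<sub>l</sub>(x, y) = exp(−((x − x<sub>l</sub>)² + (y − y<sub>l</sub>)²) / (2σ²)),

normalized to a **maximum of 1** (not unit integral), with σ = 10 px by
default. Landmarks are recovered by per-channel argmax,

&nbsp;&nbsp;&nbsp;&nbsp;(x<sub>p</sub>, y<sub>p</sub>)<sub>l</sub> = argmax<sub>x,y</sub> H<sub>l</sub>(x, y),

at pixel resolution, with ties broken deterministically to the smallest
row, then the smallest column. No truncation radius is applied (truncation
would change the loss gradients), and no sub-pixel refinement is performed.
Coordinates are 0-based with x = column, y = row, origin at the centre of
the top-left pixel; sub-pixel landmark positions are encoded exactly (the
peak *pixel* then reads slightly below 1).

## The Flat-net generator

The heat-map generator is a fully-convolutional network that preserves the
input resolution everywhere: no pooling, no strided convolution, no
upsampling, no fully connected layers. Multi-scale context comes from five
parallel branches of two consecutive 9 × 9 convolutions, each branch at
its own dilation rate (defaults 1, 2, 4, 8, 16), concatenated and fused by
one 5 × 5 and three 1 × 1 convolutions. Activations are rectifiers except
a hyperbolic tangent on the output layer; the loss is the mean absolute
error between predicted and target heat-maps. The default filter counts
(f1 = 32, f2 = 64, f4 = 128, f5 = 128, f6 = 64) give 1 918 021 trainable
scalars per 5-output network; the trainable-parameter count of any
configuration equals the closed-form per-layer sum and is verified
programmatically in the tests.

Because the full-resolution concatenation is memory-hungry, the 21
landmarks are partitioned greedily in schema order across several
networks — at most 5 outputs each by default, giving 5 networks of sizes
[5, 5, 5, 5, 1]. The partition bound is a configuration, not a hard limit:
a single 21-output network is valid and is what the reduced-scale tests
use.

The network is implemented directly in NumPy: stride-1 zero-padded
same-size convolutions via im2col + GEMM, analytic gradients (the input
gradient of a same-padded convolution is the same-padded convolution of
the output gradient with the spatially flipped, channel-transposed
kernel), and an Adam optimiser. Gradient correctness is checked against
central finite differences in the test suite.

### Training choices

* Inputs: grayscale images repeated into 3 channels and scaled to [0, 1].
* Targets: peak-1 Gaussian stacks in [0, 1] against the tanh output
  (a `target_range=(-1, 1)` switch rescales them to the full tanh range).
* Optimiser: Adam, learning rate 10⁻³, batch size 4 (none of these are
  dictated by the architecture; they are package defaults exposed in
  `TrainConfig`).
* Validation: 5% of the training items (at least one) are set aside at
  random; training stops at `max_epochs` (default 30) or when the
  validation loss improves by less than `plateau_min_delta` (default
  10⁻⁴) for `plateau_patience` (default 5) consecutive epochs.
* Determinism: all initialisation and shuffling derives from
  `TrainConfig.rng_seed`.

An empirical property of this loss worth documenting: with MAE, "predict
zero everywhere" is a strong plateau, because the Gaussian bumps occupy a
few percent of the pixels and the absolute-error gradient has constant
magnitude. With too few filters (f1 ≤ 4) the rectifier units of the 1 × 1
layers can die against this plateau and training never escapes it; at
f1 = 8/f2 = 16 and above the feature diversity is sufficient and the loss
descends reliably. The plateau phase also means early epochs can show
validation improvements below a coarse `plateau_min_delta`; the
reduced-scale experiments therefore use a smaller `min_delta` so the
plateau-stopping rule does not fire before the descent begins.

## Augmentation

Ten fixed transforms expand a corpus of originals by ×11 (e.g.
9 subjects × 62 classes = 558 originals → 6138 items): Gaussian intensity
noise (variance 12.75 on the 0–255 scale, sd ≈ 3.57), Gaussian blur
(σ = 5 px), rotations (+10°, −5°), translations ((+30, +10), (+40, −10)
px), rotation-then-translation, zooms (0.8, 1.2 after translation, 0.9
after translation with σ = 3 px blur). Geometric components compose in the
fixed order rotation → translation → zoom about the image centre
((cols−1)/2, (rows−1)/2); positive rotation is counter-clockwise in the
displayed (x right, y down) frame, and translation (+a, +b) means
dx = +a columns, dy = +b rows. The image is resampled bilinearly with
zero padding while the landmark coordinates are mapped through the exact
affine, so annotation and image cannot drift apart; landmarks pushed
outside the frame are kept and flagged, never clamped. The blur parameters
are interpreted as standard deviations in pixels and the noise parameter
as a variance on the 8-bit scale; intensities are clipped to [0, 255]
after the photometric steps.

## Evaluation

Per test landmark, the Euclidean distance d = √((x_g−x_p)² + (y_g−y_p)²)
in pixels; aggregate accuracy as RMSE = √(mean(d²)) over coordinate-pair
errors, reported in px and (via resolution/10) in cm; and the outlier rate
as the percentage of records with d **strictly** greater than 5 px.
Two split protocols:

* **CV10** — a seeded permutation of the augmented pool chopped into k
  near-equal blocks (floor/ceil sizes; for 6138 items at k = 10 the
  smallest test fold is 613 items against 5525 training items). Items of
  the same subject and class can appear on both sides of a fold; this
  leakage is inherent to the protocol and is recorded in the manifest.
* **LoSo** — leave-one-subject-out: the test side is the held-out
  subject's *un-augmented originals* only; the train side is every item of
  the remaining subjects (8 × 62 × 11 = 5456 at the canonical corpus
  shape). Subject-disjointness is asserted at runtime.

Method comparison uses a two-sided paired t-test on distance errors
matched per (image, landmark) (delegated to `scipy.stats.ttest_rel`);
pairs with zero difference variance raise an explicit degenerate-input
error instead of fabricating a p-value.

## Phantom corpus

Real annotated vocal-tract MRI corpora are generally not shareable, so the
package ships a seeded synthetic stand-in rather than any scanner data.
The generator renders smooth bright curves on a dark background laid out
like a midsagittal head — facial profile, hard palate, tongue dorsum and
mouth floor, lips, velum, epiglottis, pharyngeal wall — as interpolating
Catmull-Rom splines rasterised with a Gaussian profile of ≈2 px width.
The 21 landmarks are placed *analytically* on the curve control points,
except the teeth points UT/LT which sit at fixed offsets from the
palate/jaw curves and are not drawn (teeth are invisible on MRI).
Variability is structured as in the real task: per-subject morphology
(global scale ±6%, position offset, palate curvature, jaw length) and
per-(subject, class) articulation (tongue-body shape, tongue-tip
elevation, jaw opening up to 4°, lip protrusion/aperture, velum angle,
larynx height), plus additive Gaussian intensity noise (sd 4 by default,
near the augmentation noise scale). Everything is a deterministic
function of the seed via per-(subject, class) child seeds.

What the phantom does **not** emulate: soft-tissue texture and intensity
inhomogeneity, scanner-dependent noise structure, touching articulators
with ambiguous boundaries, and genuinely unusual articulations. Passing
the learning tests therefore shows that the pipeline can learn
subject-generalizing landmark localization from images with the corpus
*structure* of the real task — it does not certify accuracy on clinical
MRI.

## Reduced-scale study conditions

The learning experiments in the test suite run the full LoSo protocol at a
reduced size chosen for a single-CPU environment: a 4-subject × 10-class
phantom at 48 × 48 px, σ = 5 px targets, one 21-output network with
reduced filters (8, 16, 32, 32, 16) and dilation rates (1, 2, 3, 4, 6)
scaled to the smaller frame, one held-out-subject fold with the
×11-augmented training side (330 items), batch 4, learning rate 10⁻³,
10 epochs. The single-sample overfitting check uses the same trunk but
widens the last hidden 1 × 1 layer back to the full-scale 64 channels:
when all 21 output channels share one network, a 16-channel head is
narrower than its output and caps how sharply per-channel peaks can be
memorised (16/21 landmarks within 2 px head-limited vs 21/21 with the
64-channel head), while for the *generalization* run the narrow head acts
as a useful regularizer (held-out median 4.0 px vs 5.9 px with the wide
head). The overfitting run takes 1600 Adam steps with a final
low-learning-rate phase (2 × 10⁻⁴) to settle the peak positions.
Accuracy thresholds (median held-out error < 5 px, strictly below an
untrained network; ≥ 19/21 landmarks within 2 px after overfitting) are
independent of the scaling.

A related sensitivity worth knowing: whether MAE training escapes the
all-zero plateau depends on the random initialisation draw interacting
with layer widths (e.g. at 48 × 48, the (…, 32, 64) head with one seed
learns cleanly while (…, 64, 64) with the same seed collapses). The
experiment seed is therefore part of the study conditions, and production
runs should monitor the first epochs of the loss curve for the
plateau-escape signature.

## Numerical and degenerate-input conventions

* Argmax ties: smallest row, then smallest column (NumPy row-major first
  occurrence); a constant channel decodes to (0, 0) with a degeneracy
  flag.
* Encoding a landmark outside the frame raises unless the caller opts
  into skip-with-warning (training opts in, since augmented copies may
  push landmarks out).
* Empty corpora, single-subject LoSo, k < 2 CV, zero-variance t-test
  pairs, and non-positive zoom scales raise errors rather than degrade.
* CSV round-trips use full-precision floats (`float_precision=
  "round_trip"` on read); images are 8-bit PNG, exact for integer-valued
  data.

## Known limitations

* The phantom is schematic; see above.
* Decoding is pixel-resolution, so even a perfect model carries up to
  ~0.7 px quantisation error against sub-pixel ground truth.
* The NumPy implementation is CPU-bound; the default 256 × 256 five-network
  configuration is intended for demonstration and small studies, not
  high-throughput training.
* The evaluation harness is method-agnostic (any predictor that maps an
  image to 21 coordinates can be scored and compared), but only the
  Flat-net localizer is implemented here.
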