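# vtloc — vocal-tract landmark localization from midsagittal images

Articulatory speech research, speech-disorder diagnosis and therapy
planning all rest on measuring how the articulators surrounding the vocal
tract — tongue, lips, velum, epiglottis, larynx — deform across speakers
and speech tasks. The prerequisite for any such quantitative analysis is
identifying the same anatomical landmarks on every midsagittal image.
`vtloc` is a library + CLI that automates this for the standard catalogue
of 21 vocal-tract landmarks (ANS, EG, ET, …, VT; tongue tip `TT`, velum
tip `VT`, teeth points `UT`/`LT`, and so on), aimed at researchers working
with 2-D midsagittal grayscale images such as 256 × 256 px / 1 mm-per-px
MRI slices.

## Method

Landmark coordinates are represented as **heat-maps in channels**: for an
*N* × *N* input the model emits a tensor *H* ∈ ℝ^(N×N×L), one channel per
landmark, trained against targets G_l(x, y) = exp(−((x−x_l)² + (y−y_l)²)
/ (2σ²)) — an untruncated Gaussian hat with σ = 10 px and maximum 1 —
and decoded by per-channel argmax,

    (x_p, y_p)_l = argmax_{x,y} H_l(x, y).

The generator, **Flat-net**, is fully convolutional and resolution
preserving: no pooling, no strided convolution, no upsampling, no fully
connected layers. Five parallel branches of two consecutive 9 × 9
convolutions at different dilation rates (1, 2, 4, 8, 16) read the image
at five resolutions; their feature maps are concatenated and fused by a
5 × 5 and three 1 × 1 convolutions (ReLU throughout, tanh output), with
mean-absolute-error loss. The 21 output channels are partitioned across
5 sub-networks of ≤ 5 channels each to bound memory. The network and its
training loop are implemented directly in NumPy (im2col/GEMM convolutions
with analytic gradients, Adam).

Around the model, the package provides

* a keypoint-consistent **augmentation battery** — 10 fixed
  noise/blur/rotation/translation/zoom transforms that expand a corpus
  ×11 and map the landmark coordinates through the exact same affine as
  the image;
* a seeded **synthetic phantom generator** — schematic midsagittal-like
  images (subjects × articulation classes) with analytically placed
  ground-truth landmarks, standing in for clinical corpora that cannot be
  shared;
* an **evaluation harness** — Euclidean distances, RMSE in px and cm,
  the >5 px outlier rate, per-landmark/per-subject matrices, randomized
  10-fold cross-validation and leave-one-subject-out (LoSo) protocols,
  and paired t-tests for method comparison.

See `docs/methods.md` for the full model description, parameter defaults
and design decisions.

## Worked example

Generate a phantom corpus, expand it ×11, and run the leave-one-subject-out
pipeline end to end (synthesize → augment → split → train → predict →
report):

```python
from vtloc import ExperimentConfig, PhantomConfig, run_experiment
from vtloc.flatnet import FlatNetConfig, TrainConfig
from vtloc.heatmap import CodecConfig

config = ExperimentConfig(
    scheme="LoSo",
    phantom=PhantomConfig(n_subjects=3, n_classes=10, image_size=(48, 48),
                          rng_seed=7),
    flatnet=FlatNetConfig(branch_dilation_rates=(1, 2, 3, 4, 6),
                          filters_l1=8, filters_l2=16, filters_l4=32,
                          filters_l5=32, filters_l6=16),
    train=TrainConfig(max_epochs=10, batch_size=4, learning_rate=1e-3,
                      plateau_min_delta=1e-6, rng_seed=0),
    codec=CodecConfig(sigma_px=5.0),
    max_per_network=21,
    seed=7,
)
report = run_experiment(config)
print(f"overall RMSE: {report.overall_rmse_px:.2f} px "
      f"/ {report.overall_rmse_cm:.3f} cm")
print(f"outlier rate (>5 px): {report.overall_outlier_pct:.1f}%")
print(report.per_subject.to_string(index=False))
```

Output (about 12 minutes on one CPU — three folds are trained from
scratch):

```
overall RMSE: 7.37 px / 0.737 cm
outlier rate (>5 px): 36.8%
subject   rmse_px  rmse_cm   n
    S00 11.394341 1.139434 210
    S01  3.966616 0.396662 210
    S02  4.173662 0.417366 210
```

The RMSE is the root mean squared coordinate-pair error over every
landmark of every held-out test image (`rmse² = mean(d²)` over Euclidean
distances d), convertible px ↔ cm through the configured resolution
(1 mm/px here, so 7.37 px = 0.737 cm); the outlier rate is the percentage
of landmarks further than 5 px from ground truth. Each fold's model never
saw the tested subject — the relevant regime for localizing landmarks on
a new speaker — and the per-subject rows show how strongly accuracy
depends on the held-out speaker at this deliberately small training size
(two subjects per fold): S01 and S02 are localized to ~4 px while the
morphologically more distinct S00 stays above 11 px. Larger corpora and
longer training (more subjects, more epochs) move all folds toward the
S01/S02 regime, as the learning tests in `tests/test_acceptance.py`
verify on a 4-subject corpus.

The same pipeline is scriptable from the shell:

```
vtloc synth --subjects 4 --classes 10 --size 64 --seed 7 --out corpus/
vtloc augment --annotations corpus/annotations.csv --images corpus/images \
      --seed 7 --out augmented/
vtloc train --annotations augmented/annotations.csv --images augmented/images \
      --epochs 10 --seed 0 --out model/
vtloc predict --model model/ --image corpus/images/S00_C000_orig.png \
      --out landmarks.csv
vtloc run-loso --config experiment.yaml --seed 7
```

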