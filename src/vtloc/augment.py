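"""Keypoint-consistent data augmentation.

Each :class:`TransformSpec` combines geometric components (rotation,
translation, zoom — composed in that fixed order about the image centre)
with photometric components (Gaussian blur, additive Gaussian intensity
noise).  The geometric part acts on the image by bilinear resampling with
zero padding and on the landmark coordinates through the *exact* same
affine map, so image and annotation never drift apart; photometric
components leave landmarks untouched.

Conventions (the transform parameters are plain signed numbers, so these
must be pinned down):

* centre of rotation/zoom = image centre ``((cols-1)/2, (rows-1)/2)``;
* positive rotation = counter-clockwise as displayed (x right, y down);
* translation ``(+a, +b)`` = ``dx = +a`` columns, ``dy = +b`` rows;
* blur/noise parameters act on the 0–255 intensity scale, with the result
  clipped back to ``[0, 255]``;
* a landmark pushed outside the frame stays at its mapped coordinates
  (flagged via :meth:`AnnotatedImage.in_frame`), never clamped.

:func:`standard_transforms` returns the fixed battery of 10 transforms
that expands a corpus of originals by a factor of 11 (originals + 10
augmented copies each), e.g. 9 subjects x 62 classes = 558 originals into
6138 items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import AnnotatedImage

__all__ = ["TransformSpec", "AugmentedCorpus", "standard_transforms",
           "apply_transform", "augment_corpus"]


@dataclass(frozen=True)
class TransformSpec:
    """One augmentation recipe.

    Components are applied in the fixed order
    rotation -> translation -> zoom -> blur -> noise.
    A component at its identity value (0 rotation, (0, 0) translation,
    zoom 1, blur 0, noise variance 0) is inactive.
    """

    name: str
    noise_variance: float = 0.0     # Gaussian intensity noise, mean 0, 8-bit units^2
    blur_sigma_px: float = 0.0      # Gaussian blur standard deviation, px
    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)   # (dx cols, dy rows)
    zoom_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.zoom_scale <= 0:
            raise ValueError("zoom_scale must be positive")
        if self.noise_variance < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_variance and blur_sigma_px must be >= 0")

    @property
    def is_geometric_identity(self) -> bool:
        return (self.rotation_deg == 0.0 and self.translation_px == (0.0, 0.0)
                and self.zoom_scale == 1.0)

    def affine(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Forward 3x3 homogeneous matrix acting on ``(x, y, 1)`` points.

        Composition is zoom @ translation @ rotation (rotation applied
        first), rotation and zoom centred on the image centre.
        """
        rows, cols = image_shape
        cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0

        def about_center(m2: np.ndarray) -> np.ndarray:
            m = np.eye(3)
            m[:2, :2] = m2
            m[:2, 2] = np.array([cx, cy]) - m2 @ np.array([cx, cy])
            return m

        th = np.deg2rad(self.rotation_deg)
        # CCW in the (x right, y down) display frame
        rot = about_center(np.array([[np.cos(th), np.sin(th)],
                                     [-np.sin(th), np.cos(th)]]))
        tra = np.eye(3)
        tra[:2, 2] = self.translation_px
        zoo = about_center(np.eye(2) * self.zoom_scale)
        return zoo @ tra @ rot


@dataclass
class AugmentedCorpus:
    """Originals plus their augmented copies, with provenance intact."""

    items: list[AnnotatedImage]
    expansion_factor: int

    def __len__(self) -> int:
        return len(self.items)

    def originals(self) -> list[AnnotatedImage]:
        return [it for it in self.items if it.augmentation_tag == "orig"]


def standard_transforms() -> list[TransformSpec]:
    """The fixed battery of 10 augmentation transforms, in canonical order.

    (1) additive Gaussian noise, variance 12.75 intensity units^2;
    (2) Gaussian blur, sigma 5 px;  (3) rotation +10 deg;
    (4) rotation -5 deg;  (5) translation (+30, +10) px;
    (6) translation (+40, -10) px;
    (7) rotation -5 deg then translation (+30, +10) px;
    (8) zoom out, scale 0.8;
    (9) translation (+30, +10) px then zoom in, scale 1.2;
    (10) translation (+40, +20) px then zoom out 0.9 then blur sigma 3 px.

    The blur parameters are standard deviations in pixels; the noise
    parameter is a variance on the 8-bit intensity scale (sd ~ 3.57).
    """
    return [
        TransformSpec("noise_var12.75", noise_variance=12.75),
        TransformSpec("blur_s5", blur_sigma_px=5.0),
        TransformSpec("rot_p10", rotation_deg=10.0),
        TransformSpec("rot_m5", rotation_deg=-5.0),
        TransformSpec("trans_p30_p10", translation_px=(30.0, 10.0)),
        TransformSpec("trans_p40_m10", translation_px=(40.0, -10.0)),
        TransformSpec("rot_m5_trans_p30_p10", rotation_deg=-5.0,
                      translation_px=(30.0, 10.0)),
        TransformSpec("zoom_0.8", zoom_scale=0.8),
        TransformSpec("trans_p30_p10_zoom_1.2", translation_px=(30.0, 10.0),
                      zoom_scale=1.2),
        TransformSpec("trans_p40_p20_zoom_0.9_blur_s3", translation_px=(40.0, 20.0),
                      zoom_scale=0.9, blur_sigma_px=3.0),
    ]


def _warp_image(image: np.ndarray, forward: np.ndarray) -> np.ndarray:
    """Resample ``image`` under the forward point map (bilinear, zero pad)."""
    inv = np.linalg.inv(forward)
    b, t = inv[:2, :2], inv[:2, 2]
    # ndimage works in (row, col) index space; our map is in (x, y) = (col, row)
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    matrix_rc = swap @ b @ swap
    offset_rc = swap @ t
    return ndimage.affine_transform(image.astype(float), matrix_rc, offset=offset_rc,
                                    order=1, mode="constant", cval=0.0)


def apply_transform(item: AnnotatedImage, spec: TransformSpec,
                    rng_seed: int = 0) -> AnnotatedImage:
    """Apply one transform jointly to image and landmarks.

    The seed fixes the noise realisation; geometry and blur are
    deterministic.  Intensities are clipped to ``[0, 255]`` at the end.
    """
    image = item.image.astype(float)
    landmarks = item.landmarks.copy()
    if not spec.is_geometric_identity:
        fwd = spec.affine(item.shape)
        image = _warp_image(image, fwd)
        hom = np.concatenate([landmarks, np.ones((len(landmarks), 1))], axis=1)
        landmarks = (hom @ fwd.T)[:, :2]
    if spec.blur_sigma_px > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.blur_sigma_px)
    if spec.noise_variance > 0:
        rng = np.random.default_rng(rng_seed)
        image = image + rng.normal(0.0, np.sqrt(spec.noise_variance), size=image.shape)
    image = np.clip(image, 0.0, 255.0)
    return item.copy_with(image=image, landmarks=landmarks,
                          augmentation_tag=spec.name)


def augment_corpus(corpus: list[AnnotatedImage], seed: int = 0) -> AugmentedCorpus:
    """Expand a corpus of originals by the 10 standard transforms (x11).

    Every input must carry ``augmentation_tag == "orig"``; the output holds
    each original followed by its 10 augmented copies, all sharing the
    original's ``source_id``.  Deterministic for a fixed seed.
    """
    if not corpus:
        raise ValueError("cannot augment an empty corpus")
    bad = [it.key for it in corpus if it.augmentation_tag != "orig"]
    if bad:
        raise ValueError(f"corpus must contain originals only; already augmented: {bad[:3]}")
    specs = standard_transforms()
    ss = np.random.SeedSequence(seed)
    items: list[AnnotatedImage] = []
    for i, item in enumerate(corpus):
        items.append(item)
        for j, spec in enumerate(specs):
            child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i, j))
            item_seed = int(child.generate_state(1)[0] % (2 ** 31))
            items.append(apply_transform(item, spec, rng_seed=item_seed))
    return AugmentedCorpus(items=items, expansion_factor=len(specs) + 1)
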