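"""Corpus containers and on-disk formats.

A corpus is a list of :class:`AnnotatedImage`: one grayscale image plus its
21 landmark coordinates and provenance (subject, articulation class,
augmentation tag).  On disk a corpus is a directory of 8-bit grayscale PNG
files plus a single CSV annotation file with one row per image::

    image,subject,class,tag,source,x_ANS,y_ANS,...,x_VT,y_VT

Coordinates are stored as floats (augmented landmarks carry sub-pixel
precision); pixel data round-trips losslessly for integer-valued 8-bit
images.  Landmarks pushed outside the frame by an augmentation are kept
as-is, never clamped — consumers query :meth:`AnnotatedImage.in_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .schema import LandmarkSchema, load_schema

__all__ = [
    "AnnotatedImage",
    "read_corpus",
    "write_corpus",
    "to_three_channel",
    "px_to_cm",
]


@dataclass
class AnnotatedImage:
    """One grayscale image with its landmark annotation and provenance.

    Parameters
    ----------
    image
        2-D array of intensities in ``[0, 255]`` (rows x cols).
    landmarks
        ``(L, 2)`` float array of ``(x, y)`` = (column, row) coordinates in
        schema order.
    subject_id, class_id
        Speaker and articulation-class identifiers.
    augmentation_tag
        ``"orig"`` for an un-augmented image, else the transform name.
    source_id
        Identifier of the un-augmented original this item derives from;
        augmented copies share it with their original.
    resolution_mm_per_px
        Physical pixel size; 1.0 for the 256 x 256 mm / 256 x 256 px
        acquisition geometry this package was designed around.
    """

    image: np.ndarray
    landmarks: np.ndarray
    subject_id: str
    class_id: str
    augmentation_tag: str = "orig"
    source_id: str = ""
    resolution_mm_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.image.shape}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image intensities must be finite")
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise ValueError("landmarks must have shape (L, 2)")
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError("landmark coordinates must be finite")
        if not self.source_id:
            self.source_id = f"{self.subject_id}_{self.class_id}"

    @property
    def key(self) -> str:
        """Unique identifier within a corpus."""
        return f"{self.subject_id}_{self.class_id}_{self.augmentation_tag}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # (rows, cols)

    def in_frame(self) -> np.ndarray:
        """Boolean mask of landmarks inside ``[0, cols) x [0, rows)``."""
        rows, cols = self.image.shape
        x, y = self.landmarks[:, 0], self.landmarks[:, 1]
        return (x >= 0) & (x < cols) & (y >= 0) & (y < rows)

    def copy_with(self, **changes) -> "AnnotatedImage":
        return replace(self, **changes)


def _columns(schema: LandmarkSchema) -> list[str]:
    cols = ["image", "subject", "class", "tag", "source"]
    for abbr in schema.abbreviations:
        cols += [f"x_{abbr}", f"y_{abbr}"]
    return cols


def write_corpus(corpus: list[AnnotatedImage], annotations_path, images_dir,
                 schema: LandmarkSchema | None = None) -> None:
    """Write a corpus as PNG images plus one CSV annotation file.

    Images are stored as 8-bit grayscale PNG; intensities are rounded and
    clipped to ``[0, 255]``.  Raises ``ValueError`` on an empty corpus.
    """
    if not corpus:
        raise ValueError("cannot write an empty corpus")
    schema = schema or load_schema()
    images_dir = Path(images_dir)
    images_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for item in corpus:
        if item.landmarks.shape[0] != len(schema):
            raise ValueError(
                f"item {item.key}: expected {len(schema)} landmarks, "
                f"got {item.landmarks.shape[0]}")
        fname = f"{item.key}.png"
        arr = np.clip(np.rint(item.image), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(images_dir / fname)
        row: dict[str, object] = {
            "image": fname, "subject": item.subject_id, "class": item.class_id,
            "tag": item.augmentation_tag, "source": item.source_id,
        }
        for j, abbr in enumerate(schema.abbreviations):
            row[f"x_{abbr}"] = item.landmarks[j, 0]
            row[f"y_{abbr}"] = item.landmarks[j, 1]
        rows.append(row)
    pd.DataFrame(rows, columns=_columns(schema)).to_csv(annotations_path, index=False)


def read_corpus(annotations_path, images_dir,
                schema: LandmarkSchema | None = None,
                resolution_mm_per_px: float = 1.0) -> list[AnnotatedImage]:
    """Read a corpus written by :func:`write_corpus` (or hand-prepared).

    Accepts PNG or TIFF images.  A malformed row (wrong column set, missing
    image file, non-numeric coordinate) aborts with an error naming the row.
    """
    schema = schema or load_schema()
    annotations_path = Path(annotations_path)
    if not annotations_path.exists():
        raise FileNotFoundError(str(annotations_path))
    images_dir = Path(images_dir)
    df = pd.read_csv(annotations_path, dtype={"subject": str, "class": str},
                     float_precision="round_trip")
    expected = _columns(schema)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    coord_cols = expected[5:]
    corpus = []
    for i, rec in df.iterrows():
        coords = rec[coord_cols].to_numpy()
        try:
            coords = coords.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i} ({rec['image']}): non-numeric coordinate") from exc
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"row {i} ({rec['image']}): non-finite coordinate")
        img_path = images_dir / str(rec["image"])
        if not img_path.exists():
            raise FileNotFoundError(f"row {i}: image file not found: {img_path}")
        with Image.open(img_path) as im:
            image = np.asarray(im.convert("I")).astype(float)
        corpus.append(AnnotatedImage(
            image=image,
            landmarks=coords.reshape(len(schema), 2),
            subject_id=str(rec["subject"]),
            class_id=str(rec["class"]),
            augmentation_tag=str(rec["tag"]),
            source_id=str(rec["source"]),
            resolution_mm_per_px=resolution_mm_per_px,
        ))
    return corpus


def to_three_channel(image: np.ndarray) -> np.ndarray:
    """Convert a grayscale grid to grayscale RGB by channel repetition.

    Networks in this package take 3-channel input; a grayscale image is
    repeated into each channel.  Output shape is ``(rows, cols, 3)``.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return np.repeat(image[:, :, None], 3, axis=2)


def px_to_cm(distance_px: float, resolution_mm_per_px: float = 1.0) -> float:
    """Convert a pixel distance to centimetres.

    At the study geometry of 1 mm/px, 3.6 px = 0.36 cm.
    """
    distance_px = np.asarray(distance_px, dtype=float)
    if np.any(distance_px < 0):
        raise ValueError("distance must be non-negative")
    if resolution_mm_per_px <= 0:
        raise ValueError("resolution must be positive")
    out = distance_px * resolution_mm_per_px / 10.0
    return float(out) if out.ndim == 0 else out
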