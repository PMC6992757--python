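"""Evaluation metrics, split protocols and report assembly.

Per test landmark the Euclidean distance between ground truth ``(x_g,
y_g)`` and prediction ``(x_p, y_p)`` is

    d = sqrt((x_g - x_p)^2 + (y_g - y_p)^2)   [pixels]

and the aggregate accuracy is the RMSE over coordinate-pair errors

    RMSE = sqrt( (1/Q) * sum_q [ (x_g - x_p)_q^2 + (y_g - y_p)_q^2 ] )

(equivalently ``sqrt(mean(d^2))``), reported both in pixels and — via the
image resolution — in centimetres.  A landmark with a distance error
*strictly* greater than 5 px counts as an outlier; the outlier rate is the
percentage of such records.

Two split protocols are provided:

* **CV10** — the augmented pool is randomly partitioned into 10 near-equal
  groups, each serving once as the test set.  Same-subject and same-class
  items can land on both sides of a fold; that leakage is inherent to the
  protocol and recorded in the manifest.
* **LoSo** — leave-one-subject-out: each fold tests the *un-augmented
  originals* of one subject and trains on all items (originals plus
  augmented copies) of every other subject, so train and test are
  subject-disjoint.

Method comparison uses a two-sided paired t-test on distance errors
matched per (image, landmark); pairs with zero difference variance raise
:class:`DegenerateInputError` rather than fabricate a p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .augment import AugmentedCorpus
from .io import AnnotatedImage, px_to_cm
from .schema import load_schema

__all__ = ["DistanceRecord", "SplitPlan", "EvaluationReport",
           "DegenerateInputError", "euclidean_distance", "rmse",
           "outlier_rate", "make_cv_splits", "make_loso_splits",
           "paired_ttest", "build_report"]

OUTLIER_THRESHOLD_PX = 5.0


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass(frozen=True)
class DistanceRecord:
    """Error of one predicted landmark on one test image."""

    image_id: str
    subject_id: str
    landmark: str
    dx: float     # x_g - x_p
    dy: float     # y_g - y_p

    @property
    def d(self) -> float:
        return float(np.hypot(self.dx, self.dy))


@dataclass(frozen=True)
class SplitPlan:
    """Fold assignments for one evaluation scheme.

    ``folds`` is a list of ``(train_ids, test_ids)`` tuples of item keys.
    """

    scheme: str                       # "CV10" or "LoSo"
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    rng_seed: int | None = None

    def manifest(self) -> dict:
        return {"scheme": self.scheme, "rng_seed": self.rng_seed,
                "folds": [{"train": list(tr), "test": list(te)}
                          for tr, te in self.folds]}


def euclidean_distance(gt, pred) -> float:
    """Euclidean distance in pixels between a ground-truth and a predicted point."""
    gt = np.asarray(gt, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if not (np.all(np.isfinite(gt)) and np.all(np.isfinite(pred))):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(gt[0] - pred[0], gt[1] - pred[1]))


def _as_error_array(records) -> np.ndarray:
    """Coerce records to an (n, 2) array of (dx, dy) coordinate errors."""
    if len(records) == 0:
        raise ValueError("no records")
    if isinstance(records[0], DistanceRecord):
        return np.array([[r.dx, r.dy] for r in records], dtype=float)
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected DistanceRecords or an (n, 2) error array")
    return arr


def rmse(records) -> float:
    """Root mean squared error over coordinate-pair errors, in pixels.

    Accepts a list of :class:`DistanceRecord` or an ``(n, 2)`` array of
    ``(dx, dy)`` errors; equals ``sqrt(mean(d^2))`` over the records.
    """
    err = _as_error_array(records)
    return float(np.sqrt(np.mean(err[:, 0] ** 2 + err[:, 1] ** 2)))


def outlier_rate(records, threshold_px: float = OUTLIER_THRESHOLD_PX) -> float:
    """Percentage of records with distance error strictly above the threshold."""
    if len(records) == 0:
        raise ValueError("no records")
    if isinstance(records[0], DistanceRecord):
        d = np.array([r.d for r in records], dtype=float)
    else:
        d = np.asarray(records, dtype=float)
        if d.ndim == 2:
            d = np.hypot(d[:, 0], d[:, 1])
    return float(100.0 * np.count_nonzero(d > threshold_px) / d.size)


def make_cv_splits(corpus: AugmentedCorpus, k: int = 10,
                   seed: int = 0) -> SplitPlan:
    """Random k-fold partition of the augmented pool.

    A seeded permutation is chopped into k blocks whose sizes differ by at
    most one (the first ``n % k`` folds take the extra item); each block
    serves once as the test set with the remainder as training.  For the
    canonical 6138-item pool at k=10 the smallest test fold holds 613
    items against 5525 training items.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    keys = [it.key for it in corpus.items]
    if len(keys) < k:
        raise ValueError(f"corpus of {len(keys)} items cannot be split {k} ways")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(keys))
    base, extra = divmod(len(keys), k)
    folds, start = [], 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        test_pos = perm[start:start + size]
        start += size
        test = tuple(keys[i] for i in test_pos)
        test_set = set(test)
        train = tuple(kk for kk in keys if kk not in test_set)
        folds.append((train, test))
    return SplitPlan(scheme="CV10", folds=tuple(folds), rng_seed=seed)


def make_loso_splits(corpus: AugmentedCorpus,
                     originals: list[AnnotatedImage] | None = None) -> SplitPlan:
    """Leave-one-subject-out folds: test on one subject's originals.

    One fold per subject.  The test side holds only the un-augmented
    originals of the held-out subject; the train side holds every item
    (originals + augmented copies) of all remaining subjects — for 9
    subjects x 62 classes x 11 expansion, 8 x 62 x 11 = 5456 training
    items per fold.  ``originals`` defaults to the originals already in
    the corpus.
    """
    items = corpus.items
    if originals is None:
        originals = corpus.originals()
    subjects = sorted({it.subject_id for it in items})
    if len(subjects) < 2:
        raise ValueError("LoSo requires at least 2 subjects")
    folds = []
    for subj in subjects:
        test = tuple(it.key for it in originals if it.subject_id == subj)
        train = tuple(it.key for it in items if it.subject_id != subj)
        folds.append((train, test))
    return SplitPlan(scheme="LoSo", folds=tuple(folds), rng_seed=None)


def paired_ttest(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided paired t-test on matched distance errors.

    ``errors_a`` and ``errors_b`` must be equal-length sequences paired by
    (image, landmark).  Raises :class:`DegenerateInputError` when the
    pairwise differences have zero variance (the statistic is undefined).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("errors_a and errors_b must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.ptp(diff) == 0.0:
        raise DegenerateInputError(
            "pairwise differences have zero variance; the paired t statistic "
            "is undefined for these inputs")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationReport:
    """Per-landmark / per-subject / overall accuracy plus split bookkeeping."""

    records: list[DistanceRecord]
    overall_rmse_px: float
    overall_rmse_cm: float
    overall_outlier_pct: float
    per_landmark: pd.DataFrame        # landmark, rmse_px, rmse_cm, outlier_pct, n
    per_subject: pd.DataFrame         # subject, rmse_px, rmse_cm, n
    resolution_mm_per_px: float
    split_manifest: dict

    def to_json(self, path) -> None:
        payload = {
            "overall_rmse_px": self.overall_rmse_px,
            "overall_rmse_cm": self.overall_rmse_cm,
            "overall_outlier_pct": self.overall_outlier_pct,
            "resolution_mm_per_px": self.resolution_mm_per_px,
            "per_landmark": self.per_landmark.to_dict(orient="records"),
            "per_subject": self.per_subject.to_dict(orient="records"),
            "records": [asdict(r) for r in self.records],
            "split_manifest": self.split_manifest,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_csv(self, per_landmark_path, per_subject_path) -> None:
        self.per_landmark.to_csv(per_landmark_path, index=False)
        self.per_subject.to_csv(per_subject_path, index=False)

    def distances(self) -> np.ndarray:
        return np.array([r.d for r in self.records])


def build_report(test_items: list[AnnotatedImage],
                 predictions: dict[str, np.ndarray],
                 split_plan: SplitPlan | None = None,
                 resolution_mm_per_px: float = 1.0) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from ground truth + predictions.

    ``predictions`` maps each test item's ``key`` to an ``(L, 2)`` array of
    predicted ``(x, y)`` coordinates in schema order.  Every test item must
    be covered.  Out-of-frame ground-truth landmarks are scored like any
    other (ground truth is ground truth).
    """
    if not test_items:
        raise ValueError("no test items")
    schema = load_schema()
    missing = [it.key for it in test_items if it.key not in predictions]
    if missing:
        raise ValueError(f"missing predictions for {len(missing)} items, "
                         f"e.g. {missing[:3]}")
    records: list[DistanceRecord] = []
    for it in test_items:
        pred = np.asarray(predictions[it.key], dtype=float)
        if pred.shape != it.landmarks.shape:
            raise ValueError(f"prediction shape mismatch for {it.key}")
        err = it.landmarks - pred
        for j, abbr in enumerate(schema.abbreviations[:len(err)]):
            records.append(DistanceRecord(
                image_id=it.key, subject_id=it.subject_id, landmark=abbr,
                dx=float(err[j, 0]), dy=float(err[j, 1])))

    def _cm(px: float) -> float:
        return px_to_cm(px, resolution_mm_per_px)

    lm_rows = []
    for abbr in schema.abbreviations:
        rs = [r for r in records if r.landmark == abbr]
        if not rs:
            continue
        r_px = rmse(rs)
        lm_rows.append({"landmark": abbr, "rmse_px": r_px, "rmse_cm": _cm(r_px),
                        "outlier_pct": outlier_rate(rs), "n": len(rs)})
    subj_rows = []
    for subj in sorted({r.subject_id for r in records}):
        rs = [r for r in records if r.subject_id == subj]
        r_px = rmse(rs)
        subj_rows.append({"subject": subj, "rmse_px": r_px, "rmse_cm": _cm(r_px),
                          "n": len(rs)})
    overall_px = rmse(records)
    return EvaluationReport(
        records=records,
        overall_rmse_px=overall_px,
        overall_rmse_cm=_cm(overall_px),
        overall_outlier_pct=outlier_rate(records),
        per_landmark=pd.DataFrame(lm_rows),
        per_subject=pd.DataFrame(subj_rows),
        resolution_mm_per_px=resolution_mm_per_px,
        split_manifest=split_plan.manifest() if split_plan else {},
    )
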